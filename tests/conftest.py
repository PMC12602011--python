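import numpy as np
import pytest

from phenorisk import MonthSeries


def make_month_series(
    values,
    observed=None,
    taxon="taxonA",
    station="R1-S1",
    region="R1",
    group="fish",
    month=6,
    first_year=2000,
):
    """Build a MonthSeries from a plain value list (None = unobserved year)."""
    vals = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    if observed is None:
        observed = ~np.isnan(vals)
    years = np.arange(first_year, first_year + len(vals))
    return MonthSeries(
        taxon=taxon,
        station=station,
        region=region,
        group=group,
        month=month,
        years=years,
        values=vals,
        observed=np.asarray(observed, dtype=bool),
    )


@pytest.fixture
def toy_series():
    return make_month_series([2.0, 2.3, 1.9, 2.4])
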