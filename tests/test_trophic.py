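"""Predator-prey pairing, logit divergence and uncertainty tests."""

import math

import numpy as np
import pytest

from phenorisk import (
    AbundanceWindow,
    MarFit,
    PredatorPreyPair,
    RiskQuery,
    build_pairs,
    divergence_model,
    logit,
    prey_window_risk,
    quasi_extinction_probability,
    scenario_risks,
    uncertainty_width,
)

LN10 = math.log(10.0)


def fit(taxon, month, U=-0.1, Q=0.04, region="R"):
    return MarFit(
        taxon=taxon, region=region, month=month, U_hat=U, Q_hat=Q
    ).collapsed_ci()


def window(months, taxon="pred", region="R", coverage=0.9):
    return AbundanceWindow(
        taxon=taxon, region=region, months=tuple(months), coverage=coverage
    )


def make_pair(pred_traj, prey_traj, region="R", predator="pred",
              pred_width=None, prey_width=None):
    pred = np.asarray(pred_traj, float)
    prey = np.asarray(prey_traj, float)
    pw = np.zeros_like(pred) if pred_width is None else np.asarray(pred_width)
    zw = np.zeros_like(prey) if prey_width is None else np.asarray(prey_width)
    return PredatorPreyPair(
        region=region, predator=predator, prey_set=("z1",),
        window=window((4, 5)), horizons=tuple(range(1, len(pred) + 1)),
        predator_baseline=pred,
        predator_best=np.clip(pred - pw / 2, 0, 1),
        predator_worst=np.clip(pred + pw / 2, 0, 1),
        prey_baseline=prey,
        prey_best=np.clip(prey - zw / 2, 0, 1),
        prey_worst=np.clip(prey + zw / 2, 0, 1),
    )


class TestLogit:
    def test_midpoint_is_zero(self):
        assert logit(0.5) == 0.0

    def test_one_tenth(self):
        assert logit(0.1) == pytest.approx(-math.log(9), rel=1e-12)

    def test_boundaries_clamped(self):
        assert logit(1.0) == pytest.approx(math.log((1 - 1e-6) / 1e-6))
        assert logit(0.0) == pytest.approx(-logit(1.0), rel=1e-9)


class TestPreyWindowRisk:
    def test_single_month_window_passes_risk_through(self):
        fits = {"z1": {4: fit("z1", 4)}}
        query = RiskQuery(a=LN10, T=5)
        out = prey_window_risk(fits, window((4,)), query)
        expected = quasi_extinction_probability(-0.1, 0.04, query)
        assert out["z1"][0] == pytest.approx(expected)

    def test_two_month_window_averages(self):
        fits = {"z1": {4: fit("z1", 4, U=-0.1), 5: fit("z1", 5, U=-0.4)}}
        query = RiskQuery(a=LN10, T=5)
        out = prey_window_risk(fits, window((4, 5)), query)
        p4 = scenario_risks(fits["z1"][4], query).p_baseline
        p5 = scenario_risks(fits["z1"][5], query).p_baseline
        assert out["z1"][0] == pytest.approx((p4 + p5) / 2)

    def test_taxa_outside_window_excluded(self):
        fits = {
            "z1": {4: fit("z1", 4)},
            "z2": {9: fit("z2", 9)},  # no modeled month in window
        }
        out = prey_window_risk(fits, window((4, 5)), RiskQuery(a=LN10, T=5))
        assert set(out) == {"z1"}

    def test_empty_after_exclusion_is_hard_failure(self):
        fits = {"z1": {9: fit("z1", 9)}}
        with pytest.raises(ValueError, match="no prey taxon"):
            prey_window_risk(fits, window((4, 5)), RiskQuery(a=LN10, T=5))

    def test_three_prey_hand_computed_means(self):
        months = (3, 4, 5)
        query = RiskQuery(a=LN10, T=5)
        fits = {
            z: {m: fit(z, m, U=u) for m in months}
            for z, u in [("z1", -0.1), ("z2", -0.2), ("z3", 0.0)]
        }
        out = prey_window_risk(fits, window(months), query)
        for z, u in [("z1", -0.1), ("z2", -0.2), ("z3", 0.0)]:
            assert out[z][0] == pytest.approx(
                quasi_extinction_probability(u, 0.04, query)
            )


class TestBuildPairs:
    def test_one_region_one_fish_three_zoop(self):
        fish = {("R", "pred"): {m: fit("pred", m) for m in (4, 5)}}
        zoop = {
            ("R", z): {m: fit(z, m) for m in (4, 5)}
            for z in ("z1", "z2", "z3")
        }
        windows = {("R", "pred"): window((4, 5))}
        pairs = build_pairs(fish, windows, zoop, horizons=range(1, 11))
        assert len(pairs) == 1
        assert pairs[0].prey_set == ("z1", "z2", "z3")
        assert len(pairs[0].predator_baseline) == 10

    def test_fish_in_two_regions_yields_two_pairs(self):
        fish = {
            (r, "pred"): {4: fit("pred", 4, region=r)} for r in ("R1", "R2")
        }
        zoop = {(r, "z1"): {4: fit("z1", 4, region=r)} for r in ("R1", "R2")}
        windows = {
            (r, "pred"): window((4,), region=r) for r in ("R1", "R2")
        }
        pairs = build_pairs(fish, windows, zoop, horizons=range(1, 6))
        assert [(p.region, p.predator) for p in pairs] == [
            ("R1", "pred"), ("R2", "pred"),
        ]

    def test_predator_without_window_skipped(self, caplog):
        fish = {("R", "pred"): {4: fit("pred", 4)}}
        zoop = {("R", "z1"): {4: fit("z1", 4)}}
        with caplog.at_level("WARNING"):
            pairs = build_pairs(fish, {}, zoop)
        assert pairs == []
        assert "no abundance window" in caplog.text

    def test_pair_table_matches_hand_assembly(self):
        query_T = 5
        fish = {("R", "pred"): {4: fit("pred", 4, U=-0.3)}}
        zoop = {
            ("R", "z1"): {4: fit("z1", 4, U=0.0)},
            ("R", "z2"): {4: fit("z2", 4, U=-0.1)},
        }
        pairs = build_pairs(
            fish, {("R", "pred"): window((4,))}, zoop, horizons=[query_T]
        )
        q = RiskQuery(a=LN10, T=query_T)
        assert pairs[0].predator_baseline[0] == pytest.approx(
            quasi_extinction_probability(-0.3, 0.04, q)
        )
        expected_prey = np.mean([
            quasi_extinction_probability(0.0, 0.04, q),
            quasi_extinction_probability(-0.1, 0.04, q),
        ])
        assert pairs[0].prey_baseline[0] == pytest.approx(expected_prey)


class TestDivergenceModel:
    def test_identical_trajectories_give_zero_gap_and_slope(self):
        traj = np.linspace(0.1, 0.4, 10)
        summaries, community = divergence_model([make_pair(traj, traj)])
        np.testing.assert_allclose(summaries[0].gap, 0.0, atol=1e-12)
        assert summaries[0].slope_gap == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(community["mean_gap"], 0.0, atol=1e-12)

    def test_noise_free_logit_slopes_recovered_exactly(self):
        t = np.arange(1, 11)
        fish_p = 1 / (1 + np.exp(-(-2.0 + 0.2 * t)))  # logit rises 0.2/yr
        prey_p = np.full(10, 1 / (1 + np.exp(2.0)))  # flat
        summaries, _ = divergence_model([make_pair(fish_p, prey_p)])
        assert summaries[0].slope_gap == pytest.approx(0.2, abs=1e-9)

    def test_label_swap_negates_slope_gap(self):
        rng = np.random.default_rng(5)
        fish_p = np.clip(np.sort(rng.random(10)), 0.01, 0.99)
        prey_p = np.clip(rng.random(10), 0.01, 0.99)
        fwd, _ = divergence_model([make_pair(fish_p, prey_p)])
        rev, _ = divergence_model([make_pair(prey_p, fish_p)])
        assert rev[0].slope_gap == pytest.approx(-fwd[0].slope_gap, rel=1e-9)

    def test_two_region_slopes_match_normal_equations(self):
        t = np.arange(1, 11)
        pairs = []
        slopes = {"R1": 0.15, "R2": -0.05}
        for region, s in slopes.items():
            fish_p = 1 / (1 + np.exp(-(-1.0 + (0.1 + s) * t)))
            prey_p = 1 / (1 + np.exp(-(-1.0 + 0.1 * t)))
            pairs.append(make_pair(fish_p, prey_p, region=region))
        summaries, community = divergence_model(pairs)
        by_region = {s.region: s.slope_gap for s in summaries}
        assert by_region["R1"] == pytest.approx(0.15, abs=1e-9)
        assert by_region["R2"] == pytest.approx(-0.05, abs=1e-9)
        comm = community.drop_duplicates("region").set_index("region")
        assert comm.loc["R1", "slope_gap"] == pytest.approx(0.15, abs=1e-9)

    def test_community_mean_gap_is_mean_of_pair_gaps(self):
        rng = np.random.default_rng(8)
        pairs = [
            make_pair(rng.random(10), rng.random(10), predator=f"p{i}")
            for i in range(3)
        ]
        _, community = divergence_model(pairs)
        for T in range(1, 11):
            expected = np.mean(
                [p.predator_baseline[T - 1] - p.prey_baseline[T - 1]
                 for p in pairs]
            )
            got = community.loc[community["horizon"] == T, "mean_gap"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_single_horizon_rejected(self):
        with pytest.raises(ValueError, match="2 horizons"):
            divergence_model([make_pair([0.2], [0.1])])


class TestUncertainty:
    def test_width_is_worst_minus_best(self):
        est = scenario_risks(
            MarFit(taxon="t", region="R", month=1, U_hat=-0.1, Q_hat=0.04,
                   U_lo=-0.2, U_hi=0.0, Q_lo=0.02, Q_hi=0.08),
            RiskQuery(a=LN10, T=5),
        )
        assert uncertainty_width(est) == pytest.approx(est.p_worst - est.p_best)
        assert uncertainty_width(est) > 0

    def test_collapsed_ci_gives_zero_width(self):
        est = scenario_risks(fit("t", 1), RiskQuery(a=LN10, T=5))
        assert uncertainty_width(est) == 0.0

    def test_wider_variance_ci_never_narrows_uncertainty(self):
        narrow = MarFit(taxon="t", region="R", month=1, U_hat=-0.1,
                        Q_hat=0.04, U_lo=-0.15, U_hi=-0.05,
                        Q_lo=0.03, Q_hi=0.05)
        wide = MarFit(taxon="t", region="R", month=1, U_hat=-0.1,
                      Q_hat=0.04, U_lo=-0.15, U_hi=-0.05,
                      Q_lo=0.01, Q_hi=0.25)
        for T in range(1, 11):
            q = RiskQuery(a=LN10, T=T)
            wn = uncertainty_width(scenario_risks(narrow, q))
            ww = uncertainty_width(scenario_risks(wide, q))
            assert ww >= wn - 1e-12
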