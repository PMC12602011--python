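"""Independent Monte-Carlo oracle for first-passage probabilities.

Simulates Brownian motion with drift U and infinitesimal variance Q on a
grid and applies the Brownian-bridge crossing correction within each step:
conditional on the step endpoints both lying above the barrier b, the
within-step crossing probability is exp(-2 (x0-b)(x1-b) / (Q dt)), which
is exact in distribution for Brownian motion at any step size. The
estimator averages per-path crossing probabilities (conditional Monte
Carlo), which is unbiased with lower variance than Bernoulli crossing
draws.

This module is deliberately independent of the package's closed-form
implementation.
"""

from __future__ import annotations

import numpy as np


def brownian_first_passage_mc(
    U: float,
    Q: float,
    a: float,
    T: float,
    n_paths: int = 100_000,
    dt: float = 0.05,
    seed: int = 0,
    chunk: int = 25_000,
) -> float:
    """P(min_{0<=t<=T} X_t <= -a) for X Brownian with drift U, variance Q."""
    if a == 0:
        return 1.0
    n_steps = max(1, int(round(T / dt)))
    step = T / n_steps
    rng = np.random.default_rng(seed)
    barrier = -a
    total = 0.0
    done = 0
    while done < n_paths:
        m = min(chunk, n_paths - done)
        inc = rng.normal(U * step, np.sqrt(Q * step), size=(m, n_steps))
        x = np.concatenate([np.zeros((m, 1)), np.cumsum(inc, axis=1)], axis=1)
        d0 = x[:, :-1] - barrier
        d1 = x[:, 1:] - barrier
        hit = (d0 <= 0) | (d1 <= 0)
        with np.errstate(over="ignore", invalid="ignore"):
            p_bridge = np.where(hit, 1.0, np.exp(-2.0 * d0 * d1 / (Q * step)))
        # per-path crossing probability: 1 - prod_t (1 - p_t)
        log_surv = np.sum(np.log1p(-np.clip(p_bridge, 0.0, 1.0 - 1e-16)), axis=1)
        log_surv[hit.any(axis=1)] = -np.inf
        total += np.sum(1.0 - np.exp(log_surv))
        done += m
    return total / n_paths
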