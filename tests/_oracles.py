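"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own closed forms: stationary rotation
shares come from literally simulating the two-state chain, and Monte Carlo
standard errors come from block means, so autocorrelation in the chain is
accounted for.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is available in CI images
    njit = lambda f: f  # noqa: E731


@njit(cache=True)
def _simulate_pair_counts(p_cc: float, p_oc: float, n_steps: int,
                          n_blocks: int, u: np.ndarray) -> np.ndarray:
    """Counts of the four (prev, cur) pair states per block.

    Returns an (n_blocks, 4) array with columns (cc, co, oc, oo); the chain
    starts in state corn and the first transition is discarded from block 0
    implicitly (negligible at these lengths).
    """
    block_len = n_steps // n_blocks
    counts = np.zeros((n_blocks, 4), dtype=np.int64)
    state = 1  # corn
    for i in range(n_steps):
        p = p_cc if state == 1 else p_oc
        new = 1 if u[i] < p else 0
        b = min(i // block_len, n_blocks - 1)
        if state == 1 and new == 1:
            counts[b, 0] += 1
        elif state == 1 and new == 0:
            counts[b, 1] += 1
        elif state == 0 and new == 1:
            counts[b, 2] += 1
        else:
            counts[b, 3] += 1
        state = new
    return counts


def chain_category_shares(p_cc: float, p_oc: float, n_steps: int = 1_000_000,
                          n_blocks: int = 100,
                          rng: np.random.Generator | None = None):
    """Brute-force stationary rotation-category shares with block-mean SEs.

    Returns (shares, ses) for (continuous corn, corn-other, continuous
    other) plus the corn share pi with its SE, as
    ((cc, rot, oo, pi), (se_cc, se_rot, se_oo, se_pi)).
    """
    rng = rng or np.random.default_rng(0)
    u = rng.random(n_steps)
    counts = _simulate_pair_counts(p_cc, p_oc, n_steps, n_blocks, u)
    totals = counts.sum(axis=1, keepdims=True)
    frac = counts / totals
    cc = frac[:, 0]
    rot = frac[:, 1] + frac[:, 2]
    oo = frac[:, 3]
    pi = frac[:, 0] + frac[:, 2]  # cur state is corn
    out, ses = [], []
    for series in (cc, rot, oo, pi):
        out.append(series.mean())
        ses.append(series.std(ddof=1) / np.sqrt(n_blocks))
    return np.array(out), np.array(ses)


def gauss_hermite_pa_prob(eta: np.ndarray, sd: float,
                          n_nodes: int = 40) -> np.ndarray:
    """Population-averaged logistic probability E[expit(eta + sd*Z)] by
    Gauss-Hermite quadrature, Z ~ N(0, 1)."""
    from scipy.special import expit
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    return (w[None, :] * expit(eta[:, None] + sd * x[None, :])).sum(axis=1)
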