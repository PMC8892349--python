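"""Monte Carlo uncertainty propagation and interval summaries.

Land-use model coefficients (rotation logits per stratum, CRE transition
logits per region) are redrawn from their asymptotic normal distributions and
the downstream pipeline — area deltas, attribution, environmental indicators,
emission ledger, fuel intensities — is recomputed per draw.  Price impacts
are held fixed at their point estimates and excluded from the propagation by
default.  Intervals are empirical 0.025/0.975 quantiles of the draws
(type-7-style linear interpolation, numpy's default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MCConfig:
    """Propagation settings."""
    n_reps: int = 1000
    seed: int = 0
    resample_rotation: bool = True
    resample_cre: bool = True

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")


@dataclass
class CISummary:
    """Per-quantity point estimate with 95% equal-tail interval."""
    table: pd.DataFrame  # quantity, point, lo, hi, n_dropped


def draw_rotation_coefs(model, rng: np.random.Generator) -> pd.DataFrame:
    """One asymptotic-normal draw of every stratum's transition coefficients."""
    coefs = model.coefs_.copy()
    for i, row in coefs.iterrows():
        s = int(row["stratum_id"])
        for cond in ("cc", "oc"):
            V = model.cov_.get((s, cond))
            if V is None:
                warnings.warn(f"stratum {s}/{cond}: no covariance; "
                              "coefficients held fixed", stacklevel=2)
                continue
            mean = np.array([row[f"b0_{cond}"], row[f"b1_{cond}"]])
            b = rng.multivariate_normal(mean, V)
            coefs.loc[i, f"b0_{cond}"], coefs.loc[i, f"b1_{cond}"] = b
    return coefs

def draw_cre_params(model, rng: np.random.Generator) -> dict:
    """One asymptotic-normal draw of every (direction, LRR) coefficient set."""
    out = {}
    for key, beta in model.params_.items():
        V = model.cov_.get(key)
        if V is None:
            warnings.warn(f"{key}: no covariance; coefficients held fixed",
                          stacklevel=2)
            out[key] = beta
        else:
            out[key] = rng.multivariate_normal(beta, V)
    return out


def propagate(state, mc: MCConfig) -> pd.DataFrame:
    """Recompute every downstream quantity for ``mc.n_reps`` coefficient
    draws.  ``state`` is a fitted :class:`rfsluc.pipeline.PipelineState`.
    Returns one row per draw."""
    rng = np.random.default_rng(mc.seed)
    rows = []
    for _ in range(mc.n_reps):
        rot_coefs = (draw_rotation_coefs(state.rotation_model, rng)
                     if mc.resample_rotation else None)
        cre_params = (draw_cre_params(state.cre_model, rng)
                      if mc.resample_cre else None)
        rows.append(state.recompute(rot_coefs, cre_params))
    return pd.DataFrame(rows)


def ci(draws: pd.DataFrame, point: dict[str, float] | None = None,
       ) -> CISummary:
    """Empirical 95% equal-tail intervals of the draws.

    NaN draws are excluded per quantity with their count reported; the point
    estimate is taken from ``point`` when provided, else the draw mean.
    """
    if len(draws) < 2:
        raise ValueError("need at least 2 draws")
    recs = []
    for col in draws.columns:
        v = draws[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        vv = v[ok]
        if len(vv) == 0:
            lo = hi = pt = np.nan
        else:
            lo = float(np.quantile(vv, 0.025))
            hi = float(np.quantile(vv, 0.975))
            pt = (point[col] if point and col in point
                  else float(vv.mean()))
        recs.append({"quantity": col, "point": pt, "lo": lo, "hi": hi,
                     "n_dropped": int((~ok).sum())})
    return CISummary(pd.DataFrame(recs))
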