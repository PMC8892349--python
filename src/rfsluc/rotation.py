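"""Price-responsive crop-rotation transition models.

Per region-by-soil stratum, two conditional logistic models are estimated on
the field panel: P(corn this year | corn last year) and P(corn this year |
other last year), each with an intercept and the log corn/alternative price
ratio as covariate.  The fitted pair (p_cc, p_oc) defines a two-state Markov
chain whose stationary pair-state distribution gives the shares of the three
rotation categories: continuous corn, corn-other rotation, continuous other.
Counterfactual deltas are differences of those distributions at factual vs
BAU prices, aggregated over field areas.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import units
from .synth import ROTATION_CATEGORIES, price_log_ratio


@dataclass
class EligibilityCriteria:
    """Field/region screens applied before model fitting.

    All comparisons are strict ("greater than"): fields above 15 acres, in
    regions where cropland exceeds 20% of area, corn exceeds 10% of cropland,
    and priced crops exceed 50% of non-corn cropland.
    """
    min_area_ha: float = units.MIN_FIELD_HA
    min_region_cropland_share: float = 0.20
    min_corn_share_of_cropland: float = 0.10
    min_priced_share_of_noncorn: float = 0.50

    def __post_init__(self):
        for name in ("min_region_cropland_share",
                     "min_corn_share_of_cropland",
                     "min_priced_share_of_noncorn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def filter_fields(panel: pd.DataFrame, criteria: EligibilityCriteria,
                  strata_meta: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, dict]:
    """Apply the eligibility screens; return the eligible panel and a tally.

    ``strata_meta`` supplies the region-level aggregates (cropland share of
    region area, priced share of non-corn cropland); the corn share of
    cropland is computed from the panel itself, area-weighted.
    """
    fields = panel.drop_duplicates("field_id")[
        ["field_id", "stratum_id", "area_ha"]]
    total_area = fields["area_ha"].sum()

    corn_area = (panel.assign(corn=(panel["crop"] == "corn")
                              * panel["area_ha"])
                 .groupby("stratum_id")[["corn", "area_ha"]].sum())
    corn_share = (corn_area["corn"] / corn_area["area_ha"]).rename(
        "corn_share")
    meta = strata_meta.set_index("stratum_id").join(corn_share)

    def screen(values, threshold):
        # thresholds are strict ("greater than"); a zero threshold disables
        # the screen entirely
        if threshold == 0:
            return pd.Series(True, index=values.index)
        return values > threshold

    ok_strata = meta.index[
        screen(meta["region_cropland_share"],
               criteria.min_region_cropland_share)
        & screen(meta["corn_share"], criteria.min_corn_share_of_cropland)
        & screen(meta["priced_share_of_noncorn"],
                 criteria.min_priced_share_of_noncorn)]

    area_ok = screen(fields["area_ha"], criteria.min_area_ha)
    stratum_ok = fields["stratum_id"].isin(ok_strata)
    eligible_ids = fields.loc[area_ok & stratum_ok, "field_id"]
    eligible = panel[panel["field_id"].isin(eligible_ids)]

    kept = fields["field_id"].isin(eligible_ids)
    tally = {
        "n_fields": int(len(fields)),
        "n_retained": int(kept.sum()),
        "n_excluded_area": int((~area_ok).sum()),
        "n_excluded_stratum": int((area_ok & ~stratum_ok).sum()),
        "area_share_retained": float(
            fields.loc[kept, "area_ha"].sum() / total_area)
        if total_area > 0 else 0.0,
    }
    return eligible, tally


# ----------------------------------------------------------------------
@dataclass
class RotationDistribution:
    """Stationary description of the two-state (corn/other) rotation chain."""
    p_cc: float
    p_oc: float
    pi_corn: float
    shares: dict[str, float]


def rotation_distribution(p_cc: float, p_oc: float) -> RotationDistribution:
    """Stationary corn share and rotation-category shares of the chain.

    pi = p_oc / (1 - p_cc + p_oc).  Category shares are stationary pair-state
    probabilities: continuous corn = pi*p_cc, rotated = pi*(1-p_cc) +
    (1-pi)*p_oc, continuous other = (1-pi)*(1-p_oc); they sum to one and the
    two corn categories sum to pi.
    """
    if not (0.0 <= p_cc <= 1.0 and 0.0 <= p_oc <= 1.0):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if p_cc == 1.0 and p_oc == 0.0:
        raise ValueError(
            "both states are absorbing (p_cc=1, p_oc=0): the stationary "
            "distribution depends on the initial state")
    denom = 1.0 - p_cc + p_oc
    pi = p_oc / denom if denom > 0 else 0.0
    shares = {
        "continuous_corn": pi * p_cc,
        "corn_other": pi * (1.0 - p_cc) + (1.0 - pi) * p_oc,
        "continuous_other": (1.0 - pi) * (1.0 - p_oc),
    }
    return RotationDistribution(p_cc, p_oc, pi, shares)


@dataclass
class AreaDelta:
    """Counterfactual area changes, annual means over the policy window."""
    corn_mha_per_y: float
    continuous_corn_mha: float
    rotated_corn_mha: float
    by_stratum: pd.DataFrame          # stratum_id, area_ha, d_pi, d_<category>
    category_deltas: pd.DataFrame     # stratum_id, category, d_prob, area_ha


class RotationTransitionModel(BaseEstimator):
    """Per-stratum conditional corn-transition logits.

    Fitted attributes
    -----------------
    coefs_ : DataFrame with per-stratum (b0_cc, b1_cc, b0_oc, b1_oc)
    cov_ : dict (stratum_id, cond) -> 2x2 covariance of [b0, b1]
    separation_flags_ : list of (stratum_id, cond) that fell back to the
        pooled fit because of perfect separation or a degenerate cell
    """

    def __init__(self, price_col: str = "observed"):
        self.price_col = price_col

    def fit(self, panel: pd.DataFrame, prices: pd.DataFrame, y=None):
        x = price_log_ratio(prices, self.price_col)
        trans = self._transitions(panel, x)
        strata = np.sort(trans["stratum_id"].unique())
        pooled = {}
        for cond in ("cc", "oc"):
            sub = trans[trans["prev_corn"] == (cond == "cc")]
            pooled[cond] = self._fit_logit(sub)
        rows, cov, flags = [], {}, []
        for s in strata:
            rec = {"stratum_id": s}
            for cond in ("cc", "oc"):
                sub = trans[(trans["stratum_id"] == s)
                            & (trans["prev_corn"] == (cond == "cc"))]
                res = self._fit_logit(sub)
                if res is None:
                    flags.append((int(s), cond))
                    res = pooled[cond]
                    if res is None:
                        raise ValueError(
                            f"stratum {s}: no usable observations for the "
                            f"{cond} transition and no pooled fallback")
                b, V = res
                rec[f"b0_{cond}"], rec[f"b1_{cond}"] = b
                cov[(int(s), cond)] = V
            rows.append(rec)
        self.coefs_ = pd.DataFrame(rows)
        self.cov_ = cov
        self.separation_flags_ = flags
        return self

    @staticmethod
    def _transitions(panel: pd.DataFrame, x: pd.Series) -> pd.DataFrame:
        p = panel.sort_values(["field_id", "year"])
        prev = p.groupby("field_id")["crop"].shift(1)
        ok = prev.notna()
        return pd.DataFrame({
            "stratum_id": p.loc[ok, "stratum_id"].to_numpy(),
            "prev_corn": (prev[ok] == "corn").to_numpy(),
            "corn": (p.loc[ok, "crop"] == "corn").to_numpy(),
            "x": x.reindex(p.loc[ok, "year"]).to_numpy(),
        })

    @staticmethod
    def _fit_logit(sub: pd.DataFrame):
        """Logit of corn on [1, x]; None signals separation/degeneracy."""
        if len(sub) == 0:
            return None
        yv = sub["corn"].to_numpy(dtype=float)
        if yv.min() == yv.max():
            return None  # all one outcome: perfect separation
        X = sm.add_constant(sub["x"].to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(res.params)):
                return None
            return res.params, np.asarray(res.cov_params())
        except Exception:
            return None

    # ------------------------------------------------------------------
    def probabilities(self, x: np.ndarray,
                      coefs: pd.DataFrame | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(p_cc, p_oc) arrays of shape (n_strata, len(x))."""
        c = coefs if coefs is not None else self.coefs_
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        p_cc = expit(c["b0_cc"].to_numpy()[:, None]
                     + c["b1_cc"].to_numpy()[:, None] * xv[None, :])
        p_oc = expit(c["b0_oc"].to_numpy()[:, None]
                     + c["b1_oc"].to_numpy()[:, None] * xv[None, :])
        return p_cc, p_oc

    def delta_areas(self, panel: pd.DataFrame, x_rfs: pd.Series,
                    x_bau: pd.Series, years: np.ndarray,
                    coefs: pd.DataFrame | None = None) -> AreaDelta:
        """Area-weighted counterfactual deltas, annual mean over ``years``.

        ``x_rfs``/``x_bau`` are log price-ratio series indexed by year.
        """
        return delta_areas_from_coefs(
            coefs if coefs is not None else self.coefs_,
            panel, x_rfs, x_bau, years)


def _stationary_shares(p_cc: np.ndarray, p_oc: np.ndarray) -> np.ndarray:
    """Vectorized stationary pair-state shares; output (..., 3) in the order
    of ROTATION_CATEGORIES; last axis also stores pi via shares[...,0:2]."""
    denom = np.clip(1.0 - p_cc + p_oc, 1e-12, None)
    pi = p_oc / denom
    return np.stack([
        pi * p_cc,
        pi * (1.0 - p_cc) + (1.0 - pi) * p_oc,
        (1.0 - pi) * (1.0 - p_oc),
    ], axis=-1), pi


def delta_areas_from_coefs(coefs: pd.DataFrame, panel: pd.DataFrame,
                           x_rfs: pd.Series, x_bau: pd.Series,
                           years: np.ndarray) -> AreaDelta:
    """Counterfactual rotation deltas given explicit coefficients.

    Separated from the estimator so uncertainty propagation can re-evaluate
    it cheaply for coefficient draws.
    """
    years = np.asarray(years)
    for x in (x_rfs, x_bau):
        if not set(years).issubset(set(x.index)):
            raise ValueError("price covariates must cover every delta year")
    area = (panel.drop_duplicates("field_id")
            .groupby("stratum_id")["area_ha"].sum())
    missing = set(area.index) - set(coefs["stratum_id"])
    if missing:
        raise ValueError(f"no transition fit for strata {sorted(missing)}")
    c = coefs.set_index("stratum_id").loc[area.index].reset_index()
    xr = x_rfs.reindex(years).to_numpy()
    xb = x_bau.reindex(years).to_numpy()

    def shares(x):
        p_cc = expit(c["b0_cc"].to_numpy()[:, None]
                     + c["b1_cc"].to_numpy()[:, None] * x[None, :])
        p_oc = expit(c["b0_oc"].to_numpy()[:, None]
                     + c["b1_oc"].to_numpy()[:, None] * x[None, :])
        return _stationary_shares(p_cc, p_oc)

    s_rfs, pi_rfs = shares(xr)
    s_bau, pi_bau = shares(xb)
    d_shares = (s_rfs - s_bau).mean(axis=1)      # (n_strata, 3) annual mean
    d_pi = (pi_rfs - pi_bau).mean(axis=1)
    w = area.to_numpy()

    by_stratum = pd.DataFrame({
        "stratum_id": area.index.to_numpy(),
        "area_ha": w,
        "d_pi": d_pi,
    })
    for j, cat in enumerate(ROTATION_CATEGORIES):
        by_stratum[f"d_{cat}"] = d_shares[:, j]
    cat_rows = by_stratum.melt(
        id_vars=["stratum_id", "area_ha"],
        value_vars=[f"d_{c}" for c in ROTATION_CATEGORIES],
        var_name="category", value_name="d_prob")
    cat_rows["category"] = cat_rows["category"].str.removeprefix("d_")

    corn_mha = float((w * d_pi).sum() / units.HA_PER_MHA)
    cont_mha = float((w * d_shares[:, 0]).sum() / units.HA_PER_MHA)
    # corn planted in rotation = pi*(1 - p_cc) = pi - continuous corn, so the
    # decomposition is additive by construction
    return AreaDelta(
        corn_mha_per_y=corn_mha,
        continuous_corn_mha=cont_mha,
        rotated_corn_mha=corn_mha - cont_mha,
        by_stratum=by_stratum,
        category_deltas=cat_rows,
    )


def fit_transitions(panel: pd.DataFrame, prices: pd.DataFrame,
                    price_col: str = "observed") -> RotationTransitionModel:
    """Fit the per-stratum conditional transition logits."""
    return RotationTransitionModel(price_col).fit(panel, prices)
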