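"""Cropland-extent transition models and policy attribution.

Directed land-use transitions (pasture->cropland, cropland->pasture,
CRP->cropland at contract expiry, cropland->CRP in sign-up years) are modelled
per land resource region (LRR) as logits on the return gap between cropland
and the alternative use, a soil/climate covariate, and the parcel's time-mean
return gap.  Including the time-mean is the correlated-random-effects (CRE)
device: it absorbs parcel effects that are correlated with returns, so the
coefficient on time-varying returns is not confounded by where returns are
persistently high.

Predicted deltas compare transition probabilities under factual (policy)
returns against BAU returns (crop returns deflated by the estimated price
impact), aggregated over NRI-style expansion factors.  Observed conversions
within an LRR are then attributed to the policy in proportion to the
predicted share of that region's conversion the policy explains.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

CONVERSION_DIRECTIONS = ("pasture_to_crop", "crp_to_crop")
ABANDONMENT_DIRECTIONS = ("crop_to_pasture", "crop_to_crp")
ALL_DIRECTIONS = CONVERSION_DIRECTIONS + ABANDONMENT_DIRECTIONS

_STATE_OF = {"pasture_to_crop": "pasture", "crp_to_crop": "crp",
             "crop_to_pasture": "cropland", "crop_to_crp": "cropland"}
_TARGET_OF = {"pasture_to_crop": "cropland", "crp_to_crop": "cropland",
              "crop_to_pasture": "pasture", "crop_to_crp": "crp"}
_ALT_RETURN = {"pasture_to_crop": "pasture_return",
               "crop_to_pasture": "pasture_return",
               "crp_to_crop": "crp_return", "crop_to_crp": "crp_return"}


@dataclass
class TransitionDelta:
    """Per-LRR, per-transition-base-year expected hectares, both scenarios.

    ``d_conv_ha`` is positive when the policy causes extra conversion to
    cropland; ``d_aband_ha`` is negative when the policy avoids abandonment
    (less cropland leaves under factual returns than under BAU).
    """
    table: pd.DataFrame  # lrr_id, year, conv_rfs, conv_bau, aband_rfs,
    #                      aband_bau, d_conv_ha, d_aband_ha

    @property
    def d_conversion_ha(self) -> float:
        return float(self.table["d_conv_ha"].sum())

    @property
    def d_abandonment_ha(self) -> float:
        return float(self.table["d_aband_ha"].sum())

    @property
    def avoided_abandonment_ha(self) -> float:
        return -self.d_abandonment_ha

    def by_lrr(self) -> pd.DataFrame:
        return (self.table.groupby("lrr_id")[["d_conv_ha", "d_aband_ha"]]
                .sum().reset_index())


@dataclass
class AttributionWeights:
    """Per-parcel attribution of observed conversions to the policy."""
    weights: pd.DataFrame   # parcel_id, lrr_id, area_ha, weight in [0,1]
    fractions: pd.DataFrame  # lrr_id, predicted_ha, observed_ha, fraction


class CRETransitionModel(BaseEstimator):
    """Correlated-random-effects logits for directed land-use transitions.

    Parameters
    ----------
    returns_scale : float
        Divisor for the return-gap covariate (dollars/ha per unit).
    add_time_means : bool
        Include the parcel time-mean return gap (the CRE device).  False
        gives the pooled logit that the CRE is designed to correct.

    Fitted attributes
    -----------------
    params_ : dict (direction, lrr) -> coefficients on [1, z, soil, zbar]
        (or [1, z, soil] without time means)
    cov_ : matching covariance matrices
    at_risk_ : dict direction -> at-risk frame used in fitting/prediction
    skipped_ : (direction, lrr) pairs with no usable observations
    flags_ : (direction, lrr) pairs that fell back to the pooled fit
    """

    def __init__(self, returns_scale: float = 100.0,
                 add_time_means: bool = True):
        self.returns_scale = returns_scale
        self.add_time_means = add_time_means

    # ------------------------------------------------------------------
    def _at_risk(self, panel: pd.DataFrame, direction: str) -> pd.DataFrame:
        """At-risk rows with outcome = transition occurred at the next step.

        CRP timing is respected by construction of the risk set: a
        cropland->CRP row exists only when the next year is a sign-up, a
        CRP->cropland row only when the contract expires next year.
        """
        p = panel.sort_values(["parcel_id", "year"]).copy()
        p["next_state"] = p.groupby("parcel_id")["state"].shift(-1)
        p = p[p["next_state"].notna()]
        p = p[p["state"] == _STATE_OF[direction]]
        if direction == "crop_to_crp":
            p = p[p["signup_next"].astype(bool)]
        elif direction == "crp_to_crop":
            p = p[p["crp_expiry_next"].astype(bool)]
        alt = p[_ALT_RETURN[direction]].to_numpy()
        crop = p["crop_return"].to_numpy()
        out = pd.DataFrame({
            "parcel_id": p["parcel_id"].to_numpy(),
            "lrr_id": p["lrr_id"].to_numpy(),
            "year": p["year"].to_numpy(),
            "ef": p["expansion_factor_ha"].to_numpy(),
            "crop_return": crop,
            "alt_return": alt,
            "z": (crop - alt) / self.returns_scale,
            "soil": p["soil_climate"].to_numpy(),
            "y": (p["next_state"] == _TARGET_OF[direction]).to_numpy(float),
        })
        zbar = self._time_mean_gap(panel, direction)
        out["zbar"] = zbar.reindex(out["parcel_id"]).to_numpy()
        return out

    def _time_mean_gap(self, panel: pd.DataFrame,
                       direction: str) -> pd.Series:
        z = ((panel["crop_return"] - panel[_ALT_RETURN[direction]])
             / self.returns_scale)
        return z.groupby(panel["parcel_id"]).mean()

    def _design(self, sub: pd.DataFrame,
                z: np.ndarray | None = None) -> np.ndarray:
        zv = sub["z"].to_numpy() if z is None else z
        cols = [np.ones(len(sub)), zv, sub["soil"].to_numpy()]
        if self.add_time_means:
            cols.append(sub["zbar"].to_numpy())
        return np.column_stack(cols)

    def fit(self, panel: pd.DataFrame, y=None):
        self.params_, self.cov_ = {}, {}
        self.skipped_, self.flags_ = [], []
        self.at_risk_ = {}
        for direction in ALL_DIRECTIONS:
            risk = self._at_risk(panel, direction)
            self.at_risk_[direction] = risk
            pooled = self._fit_one(risk)
            for lrr in np.sort(panel["lrr_id"].unique()):
                sub = risk[risk["lrr_id"] == lrr]
                if len(sub) == 0:
                    self.skipped_.append((direction, int(lrr)))
                    warnings.warn(
                        f"no at-risk observations for {direction} in LRR "
                        f"{lrr}; fit skipped", stacklevel=2)
                    continue
                res = self._fit_one(sub)
                if res is None:
                    self.flags_.append((direction, int(lrr)))
                    res = pooled
                if res is None:
                    self.skipped_.append((direction, int(lrr)))
                    continue
                self.params_[(direction, int(lrr))] = res[0]
                self.cov_[(direction, int(lrr))] = res[1]
        return self

    def _fit_one(self, sub: pd.DataFrame):
        """Logit fit; None signals separation or an unidentified design
        (e.g. returns constant across parcels and time)."""
        if len(sub) == 0 or sub["y"].min() == sub["y"].max():
            return None
        X = self._design(sub)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("covariates collinear/constant in a transition "
                          "cell; coefficient unidentified", stacklevel=3)
            return None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(sub["y"].to_numpy(), X,
                             family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(res.params)):
                return None
            return np.asarray(res.params), np.asarray(res.cov_params())
        except Exception:
            return None

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    # ------------------------------------------------------------------
    def predict_delta(self, corn_impact_pct: float, years,
                      params: dict | None = None) -> TransitionDelta:
        """Expected transition hectares, factual vs BAU returns.

        ``years`` are the base years of each annual transition (the first
        policy transition runs policy_year -> policy_year + 1).  BAU crop
        returns equal factual crop returns divided by (1 + impact/100);
        alternative-use returns and parcel time-means are held fixed.
        Probabilities are population-averaged (logit evaluated at covariates
        plus time-means).
        """
        self._check_fitted()
        pr = params if params is not None else self.params_
        yrs = set(int(v) for v in np.asarray(list(years)).ravel())
        panel_years = set()
        for risk in self.at_risk_.values():
            panel_years |= set(int(v) for v in risk["year"].unique())
        if not (yrs & panel_years):
            raise ValueError(
                f"requested years {sorted(yrs)} outside the panel")
        deflate = 1.0 + corn_impact_pct / 100.0
        recs = []
        for direction in ALL_DIRECTIONS:
            risk = self.at_risk_[direction]
            sub = risk[risk["year"].isin(yrs)]
            if len(sub) == 0:
                continue
            z_bau = ((sub["crop_return"].to_numpy() / deflate
                      - sub["alt_return"].to_numpy()) / self.returns_scale)
            for lrr, idx in sub.groupby("lrr_id").groups.items():
                key = (direction, int(lrr))
                if key not in pr:
                    continue
                beta = pr[key]
                grp = sub.loc[idx]
                X = self._design(grp)
                p_rfs = expit(X @ beta)
                Xb = X.copy()
                Xb[:, 1] = z_bau[sub.index.get_indexer(idx)]
                p_bau = expit(Xb @ beta)
                ef = grp["ef"].to_numpy()
                df = pd.DataFrame({
                    "year": grp["year"].to_numpy(),
                    "rfs_ha": ef * p_rfs, "bau_ha": ef * p_bau})
                agg = df.groupby("year").sum()
                for yr, row in agg.iterrows():
                    recs.append({
                        "direction": direction, "lrr_id": int(lrr),
                        "year": int(yr), "rfs_ha": row["rfs_ha"],
                        "bau_ha": row["bau_ha"],
                        "delta_ha": row["rfs_ha"] - row["bau_ha"]})
        raw = pd.DataFrame(recs)
        if raw.empty:
            raise ValueError("no at-risk observations in the requested years")
        raw["kind"] = np.where(raw["direction"].isin(CONVERSION_DIRECTIONS),
                               "conv", "aband")
        g = (raw.groupby(["lrr_id", "year", "kind"])
             [["rfs_ha", "bau_ha", "delta_ha"]].sum().unstack(
                 "kind", fill_value=0.0))

        def col(a, b):
            return (g[(a, b)] if (a, b) in g.columns
                    else pd.Series(0.0, index=g.index)).to_numpy()

        table = pd.DataFrame({
            "lrr_id": [i[0] for i in g.index],
            "year": [i[1] for i in g.index],
            "conv_rfs": col("rfs_ha", "conv"),
            "conv_bau": col("bau_ha", "conv"),
            "aband_rfs": col("rfs_ha", "aband"),
            "aband_bau": col("bau_ha", "aband"),
            "d_conv_ha": col("delta_ha", "conv"),
            "d_aband_ha": col("delta_ha", "aband"),
        })
        return TransitionDelta(table)

    # ------------------------------------------------------------------
    def avoided_abandonment_weights(self, corn_impact_pct: float, years,
                                    params: dict | None = None,
                                    ) -> pd.DataFrame:
        """Per-parcel expected avoided-abandonment weights.

        Each at-risk cropland parcel-year contributes p(BAU) - p(factual) for
        the abandonment directions; summed over years this is the parcel's
        expected avoided abandonment, and ef x weight totals the aggregate
        avoided hectares by construction.
        """
        self._check_fitted()
        pr = params if params is not None else self.params_
        yrs = set(int(v) for v in np.asarray(years).ravel())
        deflate = 1.0 + corn_impact_pct / 100.0
        parts = []
        for direction in ABANDONMENT_DIRECTIONS:
            risk = self.at_risk_[direction]
            sub = risk[risk["year"].isin(yrs)]
            if len(sub) == 0:
                continue
            z_bau = ((sub["crop_return"].to_numpy() / deflate
                      - sub["alt_return"].to_numpy()) / self.returns_scale)
            for lrr, idx in sub.groupby("lrr_id").groups.items():
                key = (direction, int(lrr))
                if key not in pr:
                    continue
                beta = pr[key]
                grp = sub.loc[idx]
                X = self._design(grp)
                p_rfs = expit(X @ beta)
                Xb = X.copy()
                Xb[:, 1] = z_bau[sub.index.get_indexer(idx)]
                p_bau = expit(Xb @ beta)
                parts.append(pd.DataFrame({
                    "parcel_id": grp["parcel_id"].to_numpy(),
                    "lrr_id": int(lrr),
                    "area_ha": grp["ef"].to_numpy(),
                    "weight": p_bau - p_rfs,
                }))
        if not parts:
            return pd.DataFrame(
                columns=["parcel_id", "lrr_id", "area_ha", "weight"])
        df = pd.concat(parts, ignore_index=True)
        return (df.groupby(["parcel_id", "lrr_id", "area_ha"],
                           as_index=False)["weight"].sum())


# ----------------------------------------------------------------------
# module-level operations
# ----------------------------------------------------------------------
def fit_cre(panel: pd.DataFrame, returns_scale: float = 100.0,
            add_time_means: bool = True) -> CRETransitionModel:
    """Fit all four directed transition models per LRR."""
    return CRETransitionModel(returns_scale, add_time_means).fit(panel)


def predict_delta(fit: CRETransitionModel, corn_impact_pct: float,
                  years) -> TransitionDelta:
    return fit.predict_delta(corn_impact_pct, years)


def net_cropland_change(delta: TransitionDelta) -> dict[str, float]:
    """Net cropland change = extra conversion + avoided abandonment (Mha)."""
    conv = delta.d_conversion_ha / 1e6
    avoided = delta.avoided_abandonment_ha / 1e6
    return {"conversion_mha": conv, "avoided_abandonment_mha": avoided,
            "net_mha": conv + avoided}


def observed_conversions(panel: pd.DataFrame, years) -> pd.DataFrame:
    """Parcels observed entering cropland from a non-crop state during the
    prediction window (base years ``years``); one row per conversion event."""
    yrs = set(int(v) for v in np.asarray(years).ravel())
    p = panel.sort_values(["parcel_id", "year"]).copy()
    p["next_state"] = p.groupby("parcel_id")["state"].shift(-1)
    ev = p[(p["year"].isin(yrs)) & (p["state"].isin(["pasture", "crp"]))
           & (p["next_state"] == "cropland")]
    return pd.DataFrame({
        "parcel_id": ev["parcel_id"].to_numpy(),
        "lrr_id": ev["lrr_id"].to_numpy(),
        "area_ha": ev["expansion_factor_ha"].to_numpy(),
        "year": ev["year"].to_numpy() + 1,
        "prior_cover": np.where(ev["state"] == "pasture", "pasture",
                                "grassland"),
    })


def attribute(delta: TransitionDelta,
              observed: pd.DataFrame) -> AttributionWeights:
    """Attribute observed conversions to the policy, per LRR.

    fraction_LRR = clamp(predicted delta / observed conversion, 0, 1); every
    observed converted parcel in the LRR carries that fraction as weight, so
    the attributed area is min(predicted, observed) in each region.
    """
    pred = delta.by_lrr().set_index("lrr_id")["d_conv_ha"]
    obs = observed.groupby("lrr_id")["area_ha"].sum()
    lrrs = sorted(set(pred.index) | set(obs.index))
    fr_rows = []
    for lrr in lrrs:
        d = float(pred.get(lrr, 0.0))
        o = float(obs.get(lrr, 0.0))
        if o <= 0.0:
            if d > 0.0:
                warnings.warn(
                    f"LRR {lrr}: predicted conversion {d:.1f} ha but none "
                    "observed; nothing to attribute onto", stacklevel=2)
            frac = 0.0
        else:
            frac = min(max(d / o, 0.0), 1.0)
        fr_rows.append({"lrr_id": lrr, "predicted_ha": d, "observed_ha": o,
                        "fraction": frac})
    fractions = pd.DataFrame(fr_rows)
    w = observed.merge(fractions[["lrr_id", "fraction"]], on="lrr_id",
                       how="left")
    weights = pd.DataFrame({
        "parcel_id": w["parcel_id"],
        "lrr_id": w["lrr_id"],
        "area_ha": w["area_ha"],
        "prior_cover": w.get("prior_cover", "grassland"),
        "weight": w["fraction"].fillna(0.0),
    })
    return AttributionWeights(weights, fractions)
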