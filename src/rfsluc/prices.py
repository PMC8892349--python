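"""Crop-price counterfactual: VAR estimation and persistent-shock removal.

The policy is treated as a persistent demand shock to crop markets.  A VAR in
log prices is estimated equation-by-equation by least squares, with a known
shock-onset date absorbed by a step dummy so the lag dynamics are not
contaminated by the structural break.  The business-as-usual (BAU) path is the
observed path minus the cumulative response of the fitted VAR to a permanent
per-period shock loading; per-crop impacts are window means of observed/BAU-1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import units


@dataclass
class ShockSpec:
    """A persistent demand shock starting at ``start_year``.

    ``loading`` is the per-period additive log-price innovation (one entry per
    crop, sign-restricted to be elementwise >= 0 in at least one entry);
    ``None`` means "use the step-dummy coefficient estimated from the data".
    ``demand_increment`` is the ethanol-demand expansion in billion gallons
    per year used for per-BGY normalization.
    """
    start_year: int
    demand_increment: float = units.DEMAND_INCREMENT_BGY
    loading: np.ndarray | None = None
    persistent: bool = True

    def __post_init__(self):
        if self.demand_increment <= 0:
            raise ValueError("demand_increment must be > 0")
        if self.loading is not None:
            self.loading = np.asarray(self.loading, dtype=float)


class VARPriceModel(BaseEstimator):
    """Vector autoregression on log crop prices with a policy step dummy.

    Parameters
    ----------
    lag_order : int
        Number of lags (default 1).
    shock_start_year : int or None
        If given, a step dummy ``1{year >= shock_start_year}`` is included in
        every equation; its coefficient vector is the estimated per-period
        shock loading.

    Fitted attributes
    -----------------
    coef_ : (k, lag_order, k) lag coefficient matrices
    intercept_ : (k,) intercepts
    shock_coef_ : (k,) estimated step-dummy loading (None without dummy)
    resid_ : (T - lag, k) residuals, for bootstrapping
    sigma_ : (k, k) residual covariance
    stable_ : bool, companion-matrix spectral radius < 1
    """

    def __init__(self, lag_order: int = 1, shock_start_year: int | None = None):
        self.lag_order = lag_order
        self.shock_start_year = shock_start_year

    # ------------------------------------------------------------------
    def fit(self, series: pd.DataFrame, y=None, price_col: str = "observed"):
        wide = series.pivot(index="crop_year", columns="crop",
                            values=price_col).sort_index()
        if wide.isna().any().any():
            raise ValueError("price series must be complete for every crop")
        if (wide <= 0).any().any():
            raise ValueError("prices must be positive")
        self.crops_ = list(wide.columns)
        self.years_ = wide.index.to_numpy()
        y_log = np.log(wide.to_numpy())
        p, k = self.lag_order, y_log.shape[1]
        T = y_log.shape[0]
        if T - p < p * k + 2:
            raise ValueError(
                f"too few observations ({T}) for a VAR({p}) in {k} series")

        rows = np.arange(p, T)
        X_parts = [np.ones((len(rows), 1))]
        for lag in range(1, p + 1):
            X_parts.append(y_log[rows - lag])
        if self.shock_start_year is not None:
            dummy = (self.years_[rows] >= self.shock_start_year
                     ).astype(float)[:, None]
            X_parts.append(dummy)
        X = np.hstack(X_parts)
        Y = y_log[rows]

        # drop zero-variance lag columns (constant series): their slope is 0
        keep = np.ones(X.shape[1], dtype=bool)
        for j in range(1, 1 + p * k):
            if np.ptp(X[:, j]) == 0.0:
                keep[j] = False
        Xk = X[:, keep]
        if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
            raise ValueError("rank-deficient VAR design matrix")
        beta_k, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
        beta = np.zeros((X.shape[1], k))
        beta[keep] = beta_k

        self.intercept_ = beta[0]
        lag_coef = beta[1:1 + p * k].T.reshape(k, p, k)
        self.coef_ = lag_coef
        self.shock_coef_ = (beta[-1] if self.shock_start_year is not None
                            else None)
        fitted = X @ beta
        self.resid_ = Y - fitted
        dof = max(len(rows) - Xk.shape[1], 1)
        self.sigma_ = self.resid_.T @ self.resid_ / dof
        self.observed_log_ = y_log
        self.spectral_radius_ = self._spectral_radius()
        self.stable_ = bool(self.spectral_radius_ < 1.0)
        if not self.stable_:
            warnings.warn(
                f"fitted VAR is non-stationary (spectral radius "
                f"{self.spectral_radius_:.3f})", stacklevel=2)
        return self

    def _spectral_radius(self) -> float:
        p, k = self.lag_order, len(self.crops_)
        comp = np.zeros((p * k, p * k))
        for lag in range(p):
            comp[:k, lag * k:(lag + 1) * k] = self.coef_[:, lag, :]
        if p > 1:
            comp[k:, :-k] = np.eye((p - 1) * k)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    # ------------------------------------------------------------------
    def cumulative_response(self, shock: ShockSpec) -> np.ndarray:
        """Per-year log-price gap implied by applying ``shock.loading`` to the
        fitted dynamics every period from ``shock.start_year``."""
        self._check_fitted()
        if not self.stable_:
            raise ValueError(
                "cumulative shock response diverges: fitted VAR is unstable")
        lam = (np.asarray(shock.loading, dtype=float)
               if shock.loading is not None else self.shock_coef_)
        if lam is None:
            raise ValueError("no shock loading: pass one or fit with a dummy")
        years = self.years_
        if shock.start_year > years[-1] or shock.start_year < years[0]:
            raise ValueError("shock start_year outside the fitted series")
        k, p = len(self.crops_), self.lag_order
        gap = np.zeros((len(years), k))
        hist = [np.zeros(k)] * p
        for t, yr in enumerate(years):
            g = sum(self.coef_[:, lag, :] @ hist[lag]
                    for lag in range(p))
            if yr >= shock.start_year:
                g = g + lam
            gap[t] = g
            hist = [g] + hist[:-1]
        return gap

    def counterfactual(self, shock: ShockSpec) -> pd.DataFrame:
        """BAU price path: observed minus the cumulative shock response.
        Pre-shock years are unchanged by construction."""
        gap = self.cumulative_response(shock)
        bau_log = self.observed_log_ - gap
        out = []
        for j, crop in enumerate(self.crops_):
            out.append(pd.DataFrame({
                "crop": crop,
                "crop_year": self.years_,
                "observed": np.exp(self.observed_log_[:, j]),
                "bau": np.exp(bau_log[:, j]),
            }))
        return pd.concat(out, ignore_index=True)

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    # ------------------------------------------------------------------
    def bootstrap_impacts(self, shock: ShockSpec,
                          window: tuple[int, int],
                          n_reps: int = 1000,
                          block_length: int | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> pd.DataFrame:
        """Residual moving-block bootstrap of the per-crop percent impacts.

        Each replicate rebuilds the observed series from resampled residual
        blocks under the fitted dynamics (including the step dummy), refits,
        and recomputes impacts.  Returns per-crop percentile CI bounds.
        """
        self._check_fitted()
        rng = rng or np.random.default_rng()
        resid = self.resid_
        n = resid.shape[0]
        L = block_length or max(2, int(round(n ** (1 / 3))))
        p, k = self.lag_order, len(self.crops_)
        draws = np.empty((n_reps, k))
        point = price_impacts(self.counterfactual(shock), window,
                              shock.demand_increment)
        use_estimated = shock.loading is None
        for r in range(n_reps):
            starts = rng.integers(0, n - L + 1, size=int(np.ceil(n / L)))
            idx = np.concatenate([np.arange(s, s + L) for s in starts])[:n]
            eps = resid[idx]
            y = self.observed_log_.copy()
            for t in range(p, len(self.years_)):
                yhat = self.intercept_.copy()
                for lag in range(p):
                    yhat += self.coef_[:, lag, :] @ y[t - 1 - lag]
                if (self.shock_coef_ is not None
                        and self.years_[t] >= self.shock_start_year):
                    yhat += self.shock_coef_
                y[t] = yhat + eps[t - p]
            series = _long_format(y, self.years_, self.crops_)
            try:
                m = VARPriceModel(self.lag_order, self.shock_start_year)
                m.fit(series, price_col="observed")
                if not m.stable_:
                    draws[r] = np.nan
                    continue
                sh = ShockSpec(shock.start_year, shock.demand_increment,
                               None if use_estimated else shock.loading)
                imp = price_impacts(m.counterfactual(sh), window,
                                    shock.demand_increment)
                draws[r] = imp.set_index("crop").loc[self.crops_,
                                                     "pct"].to_numpy()
            except (ValueError, np.linalg.LinAlgError):
                draws[r] = np.nan
        lo = np.nanpercentile(draws, 2.5, axis=0)
        hi = np.nanpercentile(draws, 97.5, axis=0)
        out = point.set_index("crop").loc[self.crops_].reset_index()
        out["ci_lo"] = lo
        out["ci_hi"] = hi
        return out


def _long_format(y_log: np.ndarray, years: np.ndarray,
                 crops: list[str]) -> pd.DataFrame:
    out = []
    for j, crop in enumerate(crops):
        out.append(pd.DataFrame({"crop": crop, "crop_year": years,
                                 "observed": np.exp(y_log[:, j])}))
    return pd.concat(out, ignore_index=True)


# ----------------------------------------------------------------------
# module-level wrappers
# ----------------------------------------------------------------------
def fit_var(series: pd.DataFrame, lag_order: int = 1,
            shock_start_year: int | None = None,
            price_col: str = "observed") -> VARPriceModel:
    """Fit the log-price VAR; see :class:`VARPriceModel`."""
    return VARPriceModel(lag_order, shock_start_year).fit(
        series, price_col=price_col)


def counterfactual_path(fit: VARPriceModel, shock: ShockSpec) -> pd.DataFrame:
    """Observed and BAU price paths implied by removing the persistent shock."""
    return fit.counterfactual(shock)


def price_impacts(paths: pd.DataFrame, window: tuple[int, int],
                  demand_increment: float = units.DEMAND_INCREMENT_BGY,
                  ) -> pd.DataFrame:
    """Per-crop mean percent price impact over an inclusive year window.

    ``pct`` is the window mean of 100*(observed/bau - 1); ``pct_per_bgy``
    divides by the demand increment in billion gallons per year.
    """
    lo, hi = window
    sel = paths[(paths["crop_year"] >= lo) & (paths["crop_year"] <= hi)]
    if sel.empty:
        raise ValueError(f"empty impact window {window}")
    g = sel.groupby("crop", sort=False).apply(
        lambda d: 100.0 * (d["observed"] / d["bau"] - 1.0).mean(),
        include_groups=False)
    out = g.rename("pct").reset_index()
    out["pct_per_bgy"] = out["pct"] / demand_increment
    return out
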