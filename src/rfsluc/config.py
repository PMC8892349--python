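"""Scenario configuration for the synthetic study system.

A :class:`ScenarioConfig` holds every ground-truth parameter of the synthetic
world: the VAR(1) process generating log crop prices, the persistent post-policy
price shock, the per-stratum rotation-transition coefficients, the per-region
correlated-random-effects land-transition coefficients, nutrient application
ratios, environmental response rates, and carbon stock distributions.  The
generators in :mod:`rfsluc.synth` consume it; recovery tests compare fitted
models against it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


# named sub-stream offsets from the master seed, one per generator, so each
# module can be regenerated independently of the others
STREAM_PRICES = 1
STREAM_FIELDS = 2
STREAM_PARCELS = 3
STREAM_NUTRIENTS = 4
STREAM_RESPONSES = 5
STREAM_CARBON = 6


def _default_var_coef() -> list[list[float]]:
    # stable 2-crop system (corn, composite other); spectral radius ~0.65
    return [[0.60, 0.10], [0.05, 0.55]]


def _default_rotation_hyper() -> dict[str, Any]:
    # logistic coefficients on [1, log(p_corn/p_other)] for the two
    # conditional transition models; per-stratum draws around these means
    return {
        "b0_cc_mean": 0.3, "b0_cc_sd": 0.25,
        "b1_cc_mean": 1.5, "b1_cc_sd": 0.25,
        "b0_oc_mean": -0.9, "b0_oc_sd": 0.25,
        "b1_oc_mean": 1.2, "b1_oc_sd": 0.25,
    }


def _default_cre_coefs() -> dict[str, Any]:
    # logit coefficients per directed transition on
    # [1, return_gap, soil_climate] plus the parcel effect
    # alpha_i = gamma * (parcel mean return gap) + N(0, re_sd)
    return {
        "pasture_to_crop": {"intercept": -2.6, "return": 0.8, "soil": 0.3},
        "crop_to_pasture": {"intercept": -3.2, "return": -0.7, "soil": -0.2},
        "crp_to_crop": {"intercept": -1.4, "return": 0.9, "soil": 0.2},
        "crop_to_crp": {"intercept": -3.6, "return": -0.6, "soil": 0.1},
        "gamma": 0.5,
        "re_sd": 0.3,
    }


def _default_nutrient_params() -> dict[str, Any]:
    # per-crop application ratios (corn normalized to 1) and corn base rates
    return {
        "n_ratio": {"corn": 1.0, "other": 0.4},
        "p_ratio": {"corn": 1.0, "other": 0.6},
        "n_base_rate": 150.0,  # kg N/ha on corn
        "p_base_rate": 25.0,   # kg P/ha on corn
    }


def _default_response_params() -> dict[str, Any]:
    """Mean per-hectare indicator rates; generator draws log-normally around
    them with the given log-sd.  Rotation rows drive the intensive margin,
    cover rows the extensive margin."""
    return {
        "log_sd": 0.08,
        "rotation": {
            # n_rate/p_rate kg/ha/y, nitrate kg N/ha/y, p_runoff kg P/ha/y,
            # erosion Mg/ha/y
            "continuous_corn": {"n_rate": 180.0, "p_rate": 28.0,
                                "nitrate_leach": 35.0, "p_runoff": 1.2,
                                "erosion": 9.0},
            "corn_other": {"n_rate": 95.0, "p_rate": 22.0,
                           "nitrate_leach": 22.0, "p_runoff": 1.0,
                           "erosion": 7.0},
            "continuous_other": {"n_rate": 60.0, "p_rate": 18.0,
                                 "nitrate_leach": 15.0, "p_runoff": 0.8,
                                 "erosion": 5.0},
        },
        "cover": {
            "cropland": {"n_rate": 120.0, "p_rate": 22.0,
                         "nitrate_leach": 25.0, "p_runoff": 1.0,
                         "erosion": 8.0},
            "pasture": {"n_rate": 10.0, "p_rate": 2.0,
                        "nitrate_leach": 4.0, "p_runoff": 0.3,
                        "erosion": 1.5},
            "grassland": {"n_rate": 0.5, "p_rate": 0.1,
                          "nitrate_leach": 2.0, "p_runoff": 0.1,
                          "erosion": 0.5},
        },
    }


def _default_carbon_params() -> dict[str, Any]:
    # per-parcel carbon stocks (Mg C/ha), log-normal families
    return {
        "biomass_log_mean": 2.0, "biomass_log_sd": 0.5,   # median ~7.4
        "soc_log_mean": 4.1, "soc_log_sd": 0.4,           # median ~60
    }


def _default_returns_params() -> dict[str, Any]:
    # $/ha annual returns by use; crop returns have a persistent parcel
    # component so that parcel effects can be made returns-correlated
    return {
        "crop_mean": 300.0, "crop_parcel_sd": 60.0, "crop_year_sd": 30.0,
        "pasture_mean": 100.0, "pasture_sd": 20.0,
        "crp_mean": 120.0, "crp_sd": 10.0,
        "scale": 100.0,  # divisor applied to the return gap covariate
    }


@dataclass
class ScenarioConfig:
    """Ground-truth parameters for one synthetic study scenario."""

    n_fields: int = 20_000
    n_parcels: int = 8_000
    n_strata: int = 6
    n_lrr: int = 7
    n_counties: int = 30

    year_start: int = 2000
    year_end: int = 2016
    policy_year: int = 2008

    crops: tuple[str, ...] = ("corn", "other")

    # log-price VAR(1): x_t = intercept + coef @ x_{t-1} + eps_t
    var_coef: list[list[float]] = field(default_factory=_default_var_coef)
    var_log_price_mean: list[float] = field(
        default_factory=lambda: [1.4, 1.9])
    var_innovation_sd: list[float] = field(
        default_factory=lambda: [0.12, 0.10])
    var_innovation_corr: float = 0.3

    # persistent log-price step from policy_year on (long-run level shift);
    # defaults reflect ~+30% corn and ~+20% other-crop price impacts
    shock_vector: list[float] = field(
        default_factory=lambda: [float(np.log(1.3)), float(np.log(1.2))])

    rotation_hyper: dict[str, Any] = field(
        default_factory=_default_rotation_hyper)
    cre_coefs: dict[str, Any] = field(default_factory=_default_cre_coefs)
    nutrient_params: dict[str, Any] = field(
        default_factory=_default_nutrient_params)
    response_params: dict[str, Any] = field(
        default_factory=_default_response_params)
    carbon_params: dict[str, Any] = field(
        default_factory=_default_carbon_params)
    returns_params: dict[str, Any] = field(
        default_factory=_default_returns_params)

    # field areas: log-normal, truncated below at the 15-acre threshold
    area_log_mean: float = 2.9
    area_log_sd: float = 0.8
    min_area_ha: float = 6.07

    # CRP machinery: entry only in sign-up years, exit only at expiry
    crp_contract_years: int = 15
    crp_signup_interval: int = 2
    crp_initial_share: float = 0.08
    pasture_initial_share: float = 0.22

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_crops(self) -> int:
        return len(self.crops)

    def rng(self, stream: int) -> np.random.Generator:
        """Named child stream of the master seed."""
        return np.random.default_rng([int(self.seed), int(stream)])

    def validate(self) -> None:
        for name in ("n_fields", "n_parcels", "n_strata", "n_lrr",
                     "n_counties"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.year_end - self.year_start < 10:
            raise ConfigError("year range must span at least 10 years")
        if not (self.year_start <= self.policy_year <= self.year_end):
            raise ConfigError("policy_year must lie inside the year range")
        a = np.asarray(self.var_coef, dtype=float)
        if a.shape != (self.n_crops, self.n_crops):
            raise ConfigError("var_coef must be n_crops x n_crops")
        rad = np.max(np.abs(np.linalg.eigvals(a)))
        if rad >= 1.0:
            raise ConfigError(
                f"VAR coefficient matrix is non-stationary "
                f"(spectral radius {rad:.3f} >= 1)")
        if len(self.shock_vector) != self.n_crops:
            raise ConfigError("shock_vector length must equal n_crops")
        if self.crp_contract_years <= 0:
            raise ConfigError("crp_contract_years must be positive")
        if self.crp_signup_interval <= 0:
            raise ConfigError("crp_signup_interval must be positive")
        for block in ("rotation", "cover"):
            for row in self.response_params[block].values():
                if any(v < 0 for v in row.values()):
                    raise ConfigError("response rates must be >= 0")
        if any(v < 0 for v in self.nutrient_params["n_ratio"].values()):
            raise ConfigError("nutrient ratios must be >= 0")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["crops"] = list(self.crops)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        if "crops" in d:
            d["crops"] = tuple(d["crops"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def signup_years(self) -> np.ndarray:
        """Calendar years in which CRP enrollment is open."""
        return np.arange(self.year_start, self.year_end + 1,
                         self.crp_signup_interval)
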