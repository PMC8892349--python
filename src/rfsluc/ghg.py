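"""Greenhouse-gas accounting and fuel carbon-intensity revision.

Covers: nonlinear N2O response to nitrogen rate (flux = exp(c0 + c1*N), an
exponential emission response convex in N), committed ecosystem-carbon
emissions from conversion (biomass + soil organic carbon losses), forgone
soil-carbon sequestration on land that would otherwise have retired to
grassland (carbon response function A*(1 - e^(-k t)) over a 15-y CRP
contract), 30-y amortization to per-litre / per-MJ fuel intensity, and
substitution of the domestic land-use-change term into published fuel-program
life-cycle intensities.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import units


@dataclass
class N2OParams:
    """Exponential N2O-N response to N rate, kg N2O-N/ha/y at N kg/ha."""
    c0: float = -0.8
    c1: float = 0.0116
    n2o_mass_ratio: float = units.N2O_MASS_RATIO
    gwp: float = units.GWP_N2O

    def __post_init__(self):
        if self.c1 <= 0:
            raise ValueError("c1 must be > 0 (emissions convex in N)")

    def flux(self, n_rate) -> np.ndarray:
        n = np.asarray(n_rate, dtype=float)
        if np.any(n < 0):
            raise ValueError("N rates must be >= 0")
        return np.exp(self.c0 + self.c1 * n)


@dataclass
class CarbonParams:
    """Ecosystem-carbon accounting parameters."""
    biomass_loss_fraction: float = 1.0
    soc_loss_fraction: float = 0.25
    crf_a: float = 12.0                # Mg C/ha asymptotic grassland SOC gain
    crf_k: float = 0.07                # 1/y carbon-response rate
    sequestration_horizon: float = 15.0  # y, one CRP contract
    amortization_years: float = 30.0
    ch4_mg_co2e_per_ha: float = 0.0    # optional methane term, Mg CO2e/ha

    def __post_init__(self):
        for name in ("biomass_loss_fraction", "soc_loss_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sequestration_horizon <= 0 or self.amortization_years <= 0:
            raise ValueError("horizon and amortization must be > 0")


@dataclass
class IntensitySpec:
    """Fuel-volume and energy conversion constants."""
    annual_ethanol_l: float = units.ANNUAL_ETHANOL_L
    lhv_mj_per_l: float = units.ETHANOL_LHV_MJ_PER_L
    gasoline_intensity: float = units.GASOLINE_G_CO2E_PER_MJ

    def __post_init__(self):
        if min(self.annual_ethanol_l, self.lhv_mj_per_l,
               self.gasoline_intensity) <= 0:
            raise ValueError("intensity constants must be > 0")


@dataclass
class EmissionLedger:
    """All policy-attributable GHG fluxes in CO2-equivalents."""
    n2o_rotation_tg_per_y: float
    n2o_extent_tg_per_y: float
    conversion_c_tg: float
    forgone_seq_tg: float

    @property
    def n2o_total_tg_per_y(self) -> float:
        return self.n2o_rotation_tg_per_y + self.n2o_extent_tg_per_y

    @property
    def total_luc_c_tg(self) -> float:
        return self.conversion_c_tg + self.forgone_seq_tg


# ----------------------------------------------------------------------
def n2o_delta(area_ha, n_rfs, n_bau, params: N2OParams) -> float:
    """Change in N2O emissions, Tg CO2e/y.

    The response is nonlinear, so factual and BAU N levels (not just their
    difference) are required: delta = sum area*(flux(N_rfs) - flux(N_bau)),
    converted N2O-N -> N2O -> CO2e.
    """
    area = np.asarray(area_ha, dtype=float)
    d_kg_n2o_n = area * (params.flux(n_rfs) - params.flux(n_bau))
    kg_co2e = d_kg_n2o_n.sum() * params.n2o_mass_ratio * params.gwp
    return float(kg_co2e / units.KG_PER_TG)


def n2o_rotation_delta(category_deltas: pd.DataFrame,
                       response: pd.DataFrame,
                       params: N2OParams) -> float:
    """N2O change from rotation shifts: each category's probability change
    weights the flux at that category's N rate (fields occupy one category
    at a time, so fluxes mix linearly in probabilities)."""
    rates = (response[response["row_type"] == "rotation"]
             .set_index("category")["n_rate"])
    joined = category_deltas.merge(rates.rename("n_rate").reset_index(),
                                   on="category")
    kg = (joined["area_ha"] * joined["d_prob"]
          * params.flux(joined["n_rate"].to_numpy())).sum()
    return float(kg * params.n2o_mass_ratio * params.gwp / units.KG_PER_TG)


def n2o_extent_delta(conversion_weights: pd.DataFrame,
                     avoided_weights: pd.DataFrame,
                     response: pd.DataFrame,
                     params: N2OParams,
                     avoided_cover: str = "grassland") -> float:
    """N2O change from extent shifts: attributed hectares move between the
    cropland N rate and the prior/counterfactual cover's N rate."""
    rates = (response[response["row_type"] == "cover"]
             .set_index("category")["n_rate"])
    total = 0.0
    frames = []
    if conversion_weights is not None and len(conversion_weights):
        frames.append(conversion_weights)
    if avoided_weights is not None and len(avoided_weights):
        frames.append(avoided_weights.assign(prior_cover=avoided_cover))
    for df in frames:
        w = (df["weight"] * df["area_ha"]).to_numpy()
        f_crop = params.flux(rates.loc["cropland"])
        f_prior = params.flux(rates.loc[df["prior_cover"]].to_numpy())
        total += float((w * (f_crop - f_prior)).sum())
    return float(total * params.n2o_mass_ratio * params.gwp
                 / units.KG_PER_TG)


def conversion_emissions(parcels: pd.DataFrame, params: CarbonParams,
                         ) -> float:
    """Committed carbon emissions from attributed conversions, Tg CO2e.

    ``parcels`` rows carry weight, area_ha, biomass_c and soc (Mg C/ha).
    """
    for col in ("biomass_c", "soc"):
        if col not in parcels or parcels[col].isna().any():
            raise ValueError(f"converted parcels missing carbon stocks "
                             f"({col})")
    w = (parcels["weight"] * parcels["area_ha"]).to_numpy()
    c_per_ha = (params.biomass_loss_fraction * parcels["biomass_c"]
                + params.soc_loss_fraction * parcels["soc"]).to_numpy()
    mg_co2e = (w * (c_per_ha * units.CO2_PER_C
                    + params.ch4_mg_co2e_per_ha)).sum()
    return float(mg_co2e * units.KG_PER_MG / units.KG_PER_TG)


def forgone_sequestration(avoided: pd.DataFrame,
                          params: CarbonParams) -> float:
    """Carbon the counterfactual grassland would have stored, Tg CO2e.

    Per hectare: A*(1 - e^(-k * horizon)) Mg C, converted to CO2.
    """
    if params.crf_k <= 0:
        raise ValueError("carbon-response rate k must be > 0")
    if avoided is None or len(avoided) == 0:
        return 0.0
    w = (avoided["weight"] * avoided["area_ha"]).to_numpy()
    soc_gain = params.crf_a * (1.0 - np.exp(
        -params.crf_k * params.sequestration_horizon))
    mg_co2e = w.sum() * soc_gain * units.CO2_PER_C
    return float(mg_co2e * units.KG_PER_MG / units.KG_PER_TG)


def total_flux(n2o_rotation_tg_per_y: float, n2o_extent_tg_per_y: float,
               conversion_c_tg: float, forgone_seq_tg: float,
               ) -> EmissionLedger:
    """Assemble the emission ledger; totals are sums of their parts."""
    return EmissionLedger(n2o_rotation_tg_per_y, n2o_extent_tg_per_y,
                          conversion_c_tg, forgone_seq_tg)


def amortized_intensity(ledger: EmissionLedger, spec: IntensitySpec,
                        include_n2o: bool = False,
                        amortization_years: float = 30.0,
                        ) -> dict[str, float]:
    """Fuel intensity of the attributed emissions, g CO2e/L and g CO2e/MJ.

    Committed land-use-change carbon is spread evenly over the amortization
    horizon; annual N2O is added un-amortized when requested; the annual
    total divides by the annual ethanol volume and the heating value.
    """
    if spec.annual_ethanol_l <= 0:
        raise ValueError("annual ethanol volume must be > 0")
    g_per_y = ledger.total_luc_c_tg * units.G_PER_TG / amortization_years
    if include_n2o:
        g_per_y += ledger.n2o_total_tg_per_y * units.G_PER_TG
    g_per_l = g_per_y / spec.annual_ethanol_l
    return {"g_per_l": g_per_l, "g_per_mj": g_per_l / spec.lhv_mj_per_l}


def substitute_domestic_luc(published_total: float,
                            published_domestic_luc: float,
                            new_domestic: float,
                            spec: IntensitySpec | None = None,
                            ) -> dict[str, float]:
    """Swap a program's domestic land-use-change term for a new estimate.

    revised = total - domestic + new_domestic (all g CO2e/MJ); the percent
    change is relative to the reference gasoline intensity.
    """
    spec = spec or IntensitySpec()
    revised = published_total - published_domestic_luc + new_domestic
    return {
        "revised_g_per_mj": revised,
        "pct_vs_gasoline": 100.0 * (revised / spec.gasoline_intensity - 1.0),
    }


def load_published_intensities() -> pd.DataFrame:
    """Published fuel-program life-cycle intensity records shipped with the
    package (EPA regulatory impact analysis, CARB LCFS, ANL GREET)."""
    with resources.files("rfsluc.data").joinpath(
            "published_intensities.csv").open() as fh:
        return pd.read_csv(fh)
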