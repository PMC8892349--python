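"""End-to-end orchestration of the counterfactual assessment.

``run_pipeline`` generates a synthetic scenario, estimates the price VAR,
rotation, and land-transition models on it, and carries the counterfactual
through nutrient/water-quality accounting and GHG/fuel-intensity accounting,
optionally with Monte Carlo uncertainty propagation.

``replicate_published`` replays the published national assessment's component
values (shipped as package data) through the same combine/normalize,
total-flux, amortization, and substitution arithmetic — a fast deterministic
check that the accounting layer reproduces the published summary numbers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import environment as env
from . import extent as ext
from . import ghg, units
from .config import ScenarioConfig
from .prices import ShockSpec, VARPriceModel, price_impacts
from .rotation import (EligibilityCriteria, RotationTransitionModel,
                       delta_areas_from_coefs, filter_fields)
from .synth import (ROTATION_CATEGORIES, gen_field_panel,
                    gen_nutrients_and_responses, gen_parcel_panel, gen_prices,
                    price_log_ratio)
from .uncertainty import MCConfig, ci, propagate


@dataclass
class PipelineState:
    """Everything needed to (re)compute the downstream quantities for a given
    set of land-use model coefficients; used both for the point estimate and
    for uncertainty propagation."""
    config: ScenarioConfig
    response: pd.DataFrame
    eligible_fields: pd.DataFrame
    x_rfs: pd.Series
    x_bau: pd.Series
    rotation_years: np.ndarray
    transition_years: np.ndarray
    rotation_model: RotationTransitionModel
    cre_model: ext.CRETransitionModel
    corn_impact_pct: float
    observed_conv: pd.DataFrame
    carbon: pd.DataFrame
    n2o_params: ghg.N2OParams = field(default_factory=ghg.N2OParams)
    carbon_params: ghg.CarbonParams = field(default_factory=ghg.CarbonParams)
    intensity_spec: ghg.IntensitySpec = field(
        default_factory=ghg.IntensitySpec)
    avoided_cover: str = "grassland"

    def recompute(self, rot_coefs: pd.DataFrame | None = None,
                  cre_params: dict | None = None) -> dict[str, float]:
        """Full downstream recomputation for one coefficient set; returns a
        flat dict of scalar outputs."""
        rot = delta_areas_from_coefs(
            rot_coefs if rot_coefs is not None
            else self.rotation_model.coefs_,
            self.eligible_fields, self.x_rfs, self.x_bau,
            self.rotation_years)
        delta = self.cre_model.predict_delta(
            self.corn_impact_pct, self.transition_years, params=cre_params)
        net = ext.net_cropland_change(delta)
        attr = ext.attribute(delta, self.observed_conv)
        conv_w = attr.weights.merge(self.carbon, on="parcel_id", how="left")
        avoided = self.cre_model.avoided_abandonment_weights(
            self.corn_impact_pct, self.transition_years, params=cre_params)

        rot_env = env.rotation_indicator_deltas(self.response,
                                                rot.category_deltas)
        ext_env = env.extent_indicator_deltas(
            self.response, conv_w, avoided, self.avoided_cover)
        n2o_rot = ghg.n2o_rotation_delta(rot.category_deltas, self.response,
                                         self.n2o_params)
        n2o_ext = ghg.n2o_extent_delta(conv_w, avoided, self.response,
                                       self.n2o_params,
                                       self.avoided_cover)
        conv_c = ghg.conversion_emissions(conv_w, self.carbon_params)
        forgone = ghg.forgone_sequestration(avoided, self.carbon_params)
        ledger = ghg.total_flux(n2o_rot, n2o_ext, conv_c, forgone)
        lint = ghg.amortized_intensity(
            ledger, self.intensity_spec, include_n2o=False,
            amortization_years=self.carbon_params.amortization_years)
        lint_n2o = ghg.amortized_intensity(
            ledger, self.intensity_spec, include_n2o=True,
            amortization_years=self.carbon_params.amortization_years)

        out = {
            "corn_area_mha": rot.corn_mha_per_y,
            "continuous_corn_mha": rot.continuous_corn_mha,
            "rotated_corn_mha": rot.rotated_corn_mha,
            "conversion_mha": net["conversion_mha"],
            "avoided_abandonment_mha": net["avoided_abandonment_mha"],
            "net_cropland_mha": net["net_mha"],
            "n2o_rotation_tg": n2o_rot,
            "n2o_extent_tg": n2o_ext,
            "n2o_total_tg": ledger.n2o_total_tg_per_y,
            "conversion_c_tg": conv_c,
            "forgone_seq_tg": forgone,
            "total_luc_c_tg": ledger.total_luc_c_tg,
            "luc_g_per_l": lint["g_per_l"],
            "luc_g_per_mj": lint["g_per_mj"],
            "luc_n2o_g_per_l": lint_n2o["g_per_l"],
            "luc_n2o_g_per_mj": lint_n2o["g_per_mj"],
        }
        for key in env.INDICATORS:
            out[f"rot_{key}"] = rot_env[key]
            out[f"ext_{key}"] = ext_env[key]
            out[f"comb_{key}"] = rot_env[key] + ext_env[key]
        return out

    # ------------------------------------------------------------------
    def factual_levels(self) -> dict[str, float]:
        """Factual-scenario indicator levels (used to back out BAU
        baselines as level minus combined delta)."""
        p_cc, p_oc = self.rotation_model.probabilities(
            self.x_rfs.reindex(self.rotation_years).to_numpy())
        denom = np.clip(1.0 - p_cc + p_oc, 1e-12, None)
        pi = p_oc / denom
        shares = np.stack([pi * p_cc,
                           pi * (1 - p_cc) + (1 - pi) * p_oc,
                           (1 - pi) * (1 - p_oc)], axis=-1).mean(axis=1)
        area = (self.eligible_fields.drop_duplicates("field_id")
                .groupby("stratum_id")["area_ha"].sum())
        coefs = self.rotation_model.coefs_.set_index("stratum_id")
        shares_df = []
        for i, s in enumerate(coefs.index):
            if s not in area.index:
                continue
            for j, cat in enumerate(ROTATION_CATEGORIES):
                shares_df.append({"stratum_id": s, "category": cat,
                                  "share": shares[i, j],
                                  "area_ha": area.loc[s]})
        shares_df = pd.DataFrame(shares_df)

        crop_ha = self._mean_cropland_ha()
        crop_df = pd.DataFrame({"area_ha": [crop_ha]})
        levels = env.observed_indicator_levels(self.response, shares_df,
                                               crop_df)
        # factual N2O level, same weighting as the indicator levels
        rot_rates = self.response[
            self.response["row_type"] == "rotation"].set_index(
                "category")["n_rate"]
        flux = self.n2o_params.flux
        lvl_n2o = float(
            (shares_df["area_ha"] * shares_df["share"]
             * flux(rot_rates.loc[shares_df["category"]].to_numpy())).sum())
        cov_rate = float(self.response[
            (self.response["row_type"] == "cover")
            & (self.response["category"] == "cropland")]["n_rate"].iloc[0])
        lvl_n2o += crop_ha * float(flux(cov_rate))
        levels["n2o_tg"] = (lvl_n2o * self.n2o_params.n2o_mass_ratio
                            * self.n2o_params.gwp / units.KG_PER_TG)
        # factual corn area (annual mean) over the eligible panel
        w = area.reindex(coefs.index).fillna(0.0).to_numpy()
        levels["corn_area_mha"] = float(
            (w * pi.mean(axis=1)).sum() / units.HA_PER_MHA)
        levels["cropland_area_mha"] = crop_ha / units.HA_PER_MHA
        return levels

    def _mean_cropland_ha(self) -> float:
        risk = self.cre_model.at_risk_["crop_to_pasture"]
        sel = risk[risk["year"].isin(self.transition_years)]
        return float(sel.groupby("year")["ef"].sum().mean())


@dataclass
class PipelineResult:
    state: PipelineState
    prices: pd.DataFrame
    paths: pd.DataFrame
    impacts: pd.DataFrame
    tally: dict
    point: dict[str, float]
    table1: env.Table1Summary
    ledger: ghg.EmissionLedger
    table2: pd.DataFrame
    truth: dict
    draws: pd.DataFrame | None = None
    ci_summary: object | None = None


def run_pipeline(config: ScenarioConfig | None = None,
                 n_reps: int = 0, mc_seed: int | None = None,
                 shock_loading: str = "config",
                 criteria: EligibilityCriteria | None = None,
                 ) -> PipelineResult:
    """Generate a scenario and run every stage on it.

    ``shock_loading`` selects how the persistent-shock loading is formed:
    "config" converts the configured long-run log-price step through the
    fitted lag dynamics, "estimated" uses the step-dummy coefficient
    estimated from the data.
    """
    config = config or ScenarioConfig()
    config.validate()

    # --- synthetic inputs -------------------------------------------------
    prices = gen_prices(config)
    fields, rotation_truth, strata_meta = gen_field_panel(config, prices)
    parcels, parcel_truth = gen_parcel_panel(config, prices)
    county, response, carbon, nutrient_truth = gen_nutrients_and_responses(
        config, fields, parcels)

    # --- price counterfactual --------------------------------------------
    var = VARPriceModel(lag_order=1,
                        shock_start_year=config.policy_year).fit(prices)
    if shock_loading == "config":
        A = var.coef_[:, 0, :]
        lam = (np.eye(config.n_crops) - A) @ np.asarray(config.shock_vector)
    elif shock_loading == "estimated":
        lam = None
    else:
        raise ValueError("shock_loading must be 'config' or 'estimated'")
    shock = ShockSpec(config.policy_year, loading=lam)
    paths = var.counterfactual(shock)
    # evaluate impacts over the post-policy years (the persistent shock is
    # in force throughout)
    window = (config.policy_year, config.year_end)
    impacts = price_impacts(paths, window)
    imp = impacts.set_index("crop")["pct"]

    # validate the nutrient inversion on the generated county table
    env.solve_crop_rates(county.head(3), config.nutrient_params["n_ratio"],
                         config.nutrient_params["p_ratio"])

    # --- rotations --------------------------------------------------------
    criteria = criteria or EligibilityCriteria()
    eligible, tally = filter_fields(fields, criteria, strata_meta)
    rot_model = RotationTransitionModel().fit(eligible, prices)
    x_rfs = price_log_ratio(prices, "observed")
    # constant-impact deflation of the price ratio in post-policy years
    shift = float(np.log((1 + imp["corn"] / 100.0)
                         / (1 + imp["other"] / 100.0)))
    x_bau = x_rfs.copy()
    post = x_bau.index >= config.policy_year
    x_bau[post] = x_bau[post] - shift
    rotation_years = np.arange(config.policy_year, config.year_end + 1)

    # --- extensive margin -------------------------------------------------
    cre_model = ext.CRETransitionModel(
        returns_scale=config.returns_params["scale"]).fit(parcels)
    transition_years = np.arange(config.policy_year, config.year_end)
    obs_conv = ext.observed_conversions(parcels, transition_years)

    state = PipelineState(
        config=config, response=response, eligible_fields=eligible,
        x_rfs=x_rfs, x_bau=x_bau, rotation_years=rotation_years,
        transition_years=transition_years, rotation_model=rot_model,
        cre_model=cre_model, corn_impact_pct=float(imp["corn"]),
        observed_conv=obs_conv, carbon=carbon)

    point = state.recompute()
    levels = state.factual_levels()

    # --- summary table ----------------------------------------------------
    rotation_deltas = {k: point[f"rot_{k}"] for k in env.INDICATORS}
    extent_deltas = {k: point[f"ext_{k}"] for k in env.INDICATORS}
    rotation_deltas["n2o_tg"] = point["n2o_rotation_tg"]
    extent_deltas["n2o_tg"] = point["n2o_extent_tg"]
    rotation_deltas["corn_area_mha"] = point["corn_area_mha"]
    extent_deltas["corn_area_mha"] = 0.0
    rotation_deltas["cropland_area_mha"] = 0.0
    extent_deltas["cropland_area_mha"] = point["net_cropland_mha"]
    baselines = {k: levels[k] - (rotation_deltas[k] + extent_deltas[k])
                 for k in rotation_deltas if k in levels}
    table1 = env.combine_and_normalize(rotation_deltas, extent_deltas,
                                       baselines)

    ledger = ghg.total_flux(point["n2o_rotation_tg"], point["n2o_extent_tg"],
                            point["conversion_c_tg"],
                            point["forgone_seq_tg"])
    table2 = build_intensity_table(point["luc_n2o_g_per_mj"])

    truth = {"rotation": rotation_truth, "cre": parcel_truth,
             "nutrients": nutrient_truth}
    result = PipelineResult(state, prices, paths, impacts, tally, point,
                            table1, ledger, table2, truth)

    if n_reps > 0:
        mc = MCConfig(n_reps=n_reps,
                      seed=config.seed if mc_seed is None else mc_seed)
        result.draws = propagate(state, mc)
        result.ci_summary = ci(result.draws, point)
    return result


# ----------------------------------------------------------------------
def build_intensity_table(new_domestic_g_per_mj: float) -> pd.DataFrame:
    """Original vs revised total fuel intensities for every published program
    whose domestic land-use-change term can be swapped out."""
    pub = ghg.load_published_intensities()
    spec = ghg.IntensitySpec()
    recs = []
    for program in pub["program"].unique():
        sub = pub[pub["program"] == program].set_index("component")
        if "total" not in sub.index or "domestic_luc" not in sub.index:
            continue
        total = float(sub.loc["total", "g_per_mj"])
        dom = float(sub.loc["domestic_luc", "g_per_mj"])
        rev = ghg.substitute_domestic_luc(total, dom, new_domestic_g_per_mj,
                                          spec)
        recs.append({
            "program": program,
            "original_g_per_mj": total,
            "original_pct_vs_gasoline": 100.0 * (
                total / spec.gasoline_intensity - 1.0),
            "revised_g_per_mj": rev["revised_g_per_mj"],
            "revised_pct_vs_gasoline": rev["pct_vs_gasoline"],
        })
    return pd.DataFrame(recs)


def load_assessment_components() -> pd.DataFrame:
    """Published national-assessment component values shipped with the
    package (component deltas, BAU baselines, carbon components)."""
    with resources.files("rfsluc.data").joinpath(
            "assessment_components.csv").open() as fh:
        return pd.read_csv(fh)


def replicate_published() -> dict[str, float]:
    """Replay the published component values through the accounting layer.

    Uses only printed component rows as inputs; every output below is
    recomputed by the same combine/normalize, total-flux, amortization, and
    substitution operations the synthetic pipeline uses.
    """
    comp = load_assessment_components().set_index("indicator")
    indicator_keys = [k for k in env.INDICATORS]
    rot = {k: float(comp.loc[k, "rotation_delta"]) for k in indicator_keys}
    extn = {k: float(comp.loc[k, "extent_delta"]) for k in indicator_keys}
    base = {k: float(comp.loc[k, "bau_baseline"]) for k in indicator_keys}
    for k, rcol, ecol in (("corn_area_mha", "rotation_delta", None),
                          ("cropland_area_mha", None, "extent_delta")):
        rot[k] = float(comp.loc[k, rcol]) if rcol else 0.0
        extn[k] = float(comp.loc[k, ecol]) if ecol else 0.0
        base[k] = float(comp.loc[k, "bau_baseline"])
    rot["n2o_tg"] = float(comp.loc["n2o_tg", "rotation_delta"])
    extn["n2o_tg"] = float(comp.loc["n2o_tg", "extent_delta"])
    base["n2o_tg"] = float(comp.loc["n2o_tg", "bau_baseline"])
    summary = env.combine_and_normalize(rot, extn, base)
    t = summary.table.set_index("indicator")

    ledger = ghg.total_flux(
        rot["n2o_tg"], extn["n2o_tg"],
        float(comp.loc["conversion_carbon_tg", "extent_delta"]),
        float(comp.loc["forgone_sequestration_tg", "extent_delta"]))
    spec = ghg.IntensitySpec()
    lint = ghg.amortized_intensity(ledger, spec, include_n2o=False)

    pub = ghg.load_published_intensities().set_index(["program", "component"])
    new_dom = float(pub.loc[("this_study", "domestic_luc"), "g_per_mj"])
    ria = ghg.substitute_domestic_luc(
        float(pub.loc[("ria", "total"), "g_per_mj"]),
        float(pub.loc[("ria", "domestic_luc"), "g_per_mj"]), new_dom, spec)
    greet = ghg.substitute_domestic_luc(
        float(pub.loc[("greet", "total"), "g_per_mj"]),
        float(pub.loc[("greet", "domestic_luc"), "g_per_mj"]), new_dom, spec)

    corn_price_pct = float(comp.loc["corn_price_pct", "extent_delta"])
    out = {
        "nitrate_combined_gg": float(t.loc["nitrate_gg", "combined"]),
        "n_applied_combined_gg": float(t.loc["n_applied_gg", "combined"]),
        "pct_n_applied": float(t.loc["n_applied_gg", "pct_of_bau"]),
        "pct_p_applied": float(t.loc["p_applied_gg", "pct_of_bau"]),
        "pct_nitrate": float(t.loc["nitrate_gg", "pct_of_bau"]),
        "pct_p_runoff": float(t.loc["p_runoff_mg", "pct_of_bau"]),
        "pct_erosion": float(t.loc["erosion_gg", "pct_of_bau"]),
        "pct_cropland": float(t.loc["cropland_area_mha", "pct_of_bau"]),
        "pct_corn_area": float(t.loc["corn_area_mha", "pct_of_bau"]),
        "pct_n2o": float(t.loc["n2o_tg", "pct_of_bau"]),
        "n2o_total_tg": ledger.n2o_total_tg_per_y,
        "n2o_rotation_share_pct": 100.0 * rot["n2o_tg"]
        / ledger.n2o_total_tg_per_y,
        "total_luc_c_tg": ledger.total_luc_c_tg,
        "luc_g_per_l": lint["g_per_l"],
        "luc_g_per_mj": lint["g_per_mj"],
        "ria_revised_g_per_mj": ria["revised_g_per_mj"],
        "ria_revised_pct_vs_gasoline": ria["pct_vs_gasoline"],
        "greet_revised_g_per_mj": greet["revised_g_per_mj"],
        "corn_price_pct_per_bgy": corn_price_pct
        / units.DEMAND_INCREMENT_BGY,
    }
    return out
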