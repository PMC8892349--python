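"""Synthetic study-system generators.

Every pipeline input is generated here with known ground truth: a factual /
counterfactual pair of crop price paths (VAR(1) in logs plus a persistent
post-policy shock), a field-level crop-sequence panel driven by price-responsive
logistic transition models, a point-level land-use panel driven by
correlated-random-effects transition models with CRP sign-up/expiry
constraints, county nutrient totals that are exactly invertible to per-crop
rates, per-rotation / per-cover environmental response rates, and per-parcel
carbon stocks.  The true parameters are returned alongside the data (and
written to ``truth.yaml``) so that estimator-recovery tests have an oracle.
"""
from __future__ import annotations

import os
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .config import (STREAM_CARBON, STREAM_FIELDS, STREAM_NUTRIENTS,
                     STREAM_PARCELS, STREAM_PRICES, STREAM_RESPONSES,
                     ScenarioConfig)

ROTATION_CATEGORIES = ("continuous_corn", "corn_other", "continuous_other")
COVERS = ("cropland", "pasture", "grassland")
CRE_DIRECTIONS = ("pasture_to_crop", "crop_to_pasture",
                  "crp_to_crop", "crop_to_crp")


# ----------------------------------------------------------------------
# prices
# ----------------------------------------------------------------------
def gen_prices(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate observed and BAU crop price paths.

    The BAU path is a stationary VAR(1) in log prices.  The observed path
    adds a deterministic persistent shock: the log-price step
    ``shock_vector`` from ``policy_year`` onward, with the same innovations
    in both paths, so observed/BAU equals exp(shock_vector) in every
    post-policy year.

    Returns a tidy frame with columns crop, crop_year, observed, bau
    (price levels).
    """
    config.validate()
    rng = config.rng(STREAM_PRICES)
    years = config.years
    k = config.n_crops
    A = np.asarray(config.var_coef, dtype=float)
    mu = np.asarray(config.var_log_price_mean, dtype=float)
    c = (np.eye(k) - A) @ mu
    sd = np.asarray(config.var_innovation_sd, dtype=float)
    corr = np.full((k, k), config.var_innovation_corr)
    np.fill_diagonal(corr, 1.0)
    cov = np.outer(sd, sd) * corr
    chol = np.linalg.cholesky(cov)

    s = np.asarray(config.shock_vector, dtype=float)

    n = len(years)
    eps = rng.standard_normal((n, k)) @ chol.T
    bau = np.empty((n, k))
    bau[0] = mu + eps[0]
    for t in range(1, n):
        bau[t] = c + A @ bau[t - 1] + eps[t]

    gap = np.where((years >= config.policy_year)[:, None], s[None, :], 0.0)
    observed = bau + gap

    rows = []
    for j, crop in enumerate(config.crops):
        rows.append(pd.DataFrame({
            "crop": crop,
            "crop_year": years,
            "observed": np.exp(observed[:, j]),
            "bau": np.exp(bau[:, j]),
        }))
    return pd.concat(rows, ignore_index=True)


def price_log_ratio(prices: pd.DataFrame, scenario: str = "observed",
                    num: str = "corn", den: str = "other") -> pd.Series:
    """log(corn price / alternative price) per crop year, the rotation
    model's price covariate."""
    wide = prices.pivot(index="crop_year", columns="crop", values=scenario)
    return np.log(wide[num] / wide[den])


# ----------------------------------------------------------------------
# field panel (crop rotations)
# ----------------------------------------------------------------------
def draw_rotation_truth(config: ScenarioConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    h = config.rotation_hyper
    s = config.n_strata
    return pd.DataFrame({
        "stratum_id": np.arange(s),
        "b0_cc": rng.normal(h["b0_cc_mean"], h["b0_cc_sd"], s),
        "b1_cc": rng.normal(h["b1_cc_mean"], h["b1_cc_sd"], s),
        "b0_oc": rng.normal(h["b0_oc_mean"], h["b0_oc_sd"], s),
        "b1_oc": rng.normal(h["b1_oc_mean"], h["b1_oc_sd"], s),
    })


def gen_field_panel(config: ScenarioConfig, prices: pd.DataFrame,
                    rotation_truth: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the field-level crop-sequence panel.

    Each field belongs to a region-by-soil stratum with its own pair of
    logistic transition models: P(corn_t | corn_{t-1}) and
    P(corn_t | other_{t-1}), both with covariate log(p_corn/p_other) at
    planting.  Field areas are log-normal truncated above the 15-acre
    eligibility threshold.

    Returns ``(panel, rotation_truth, strata_meta)`` where panel is long
    format with one row per field-year.
    """
    config.validate()
    years = config.years
    missing = set(years) - set(prices["crop_year"].unique())
    if missing:
        raise ValueError(f"prices do not cover years {sorted(missing)}")
    rng = config.rng(STREAM_FIELDS)
    if rotation_truth is None:
        rotation_truth = draw_rotation_truth(config, rng)

    nf = config.n_fields
    stratum = rng.integers(0, config.n_strata, nf)
    county = rng.integers(0, config.n_counties, nf)
    # truncated log-normal areas (resample until above threshold)
    area = np.exp(rng.normal(config.area_log_mean, config.area_log_sd, nf))
    while np.any(area <= config.min_area_ha):
        bad = area <= config.min_area_ha
        area[bad] = np.exp(rng.normal(config.area_log_mean,
                                      config.area_log_sd, bad.sum()))

    x = price_log_ratio(prices, "observed").reindex(years).to_numpy()
    tr = rotation_truth.set_index("stratum_id")
    missing_strata = set(int(s) for s in np.unique(stratum)) - set(
        int(s) for s in tr.index)
    if missing_strata:
        raise ValueError(
            f"no rotation coefficients for strata {sorted(missing_strata)}")
    b0_cc = tr["b0_cc"].to_numpy()
    b1_cc = tr["b1_cc"].to_numpy()
    b0_oc = tr["b0_oc"].to_numpy()
    b1_oc = tr["b1_oc"].to_numpy()
    # per-stratum, per-year conditional corn probabilities
    p_cc = expit(b0_cc[:, None] + b1_cc[:, None] * x[None, :])
    p_oc = expit(b0_oc[:, None] + b1_oc[:, None] * x[None, :])

    n_years = len(years)
    crops = np.empty((nf, n_years), dtype=bool)  # True = corn
    pi0 = p_oc[:, 0] / np.clip(1.0 - p_cc[:, 0] + p_oc[:, 0], 1e-12, None)
    crops[:, 0] = rng.random(nf) < pi0[stratum]
    for t in range(1, n_years):
        p = np.where(crops[:, t - 1], p_cc[stratum, t], p_oc[stratum, t])
        crops[:, t] = rng.random(nf) < p

    panel = pd.DataFrame({
        "field_id": np.repeat(np.arange(nf), n_years),
        "stratum_id": np.repeat(stratum, n_years),
        "county_id": np.repeat(county, n_years),
        "area_ha": np.repeat(area, n_years),
        "year": np.tile(years, nf),
        "crop": np.where(crops.ravel(), "corn", "other"),
    })

    strata_meta = pd.DataFrame({
        "stratum_id": np.arange(config.n_strata),
        "region_cropland_share": rng.uniform(0.3, 0.8, config.n_strata),
        "priced_share_of_noncorn": rng.uniform(0.6, 0.95, config.n_strata),
    })
    return panel, rotation_truth, strata_meta


# ----------------------------------------------------------------------
# parcel panel (extensive margin)
# ----------------------------------------------------------------------
def gen_parcel_panel(config: ScenarioConfig, prices: pd.DataFrame | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Simulate the point-level land-use panel.

    States are {cropland, pasture, crp}.  Directed transitions follow logistic
    models whose linear predictor is intercept + return-gap + soil covariate +
    a parcel effect correlated with the parcel's mean return gap (the
    correlated-random-effects structure).  CRP timing is enforced by
    construction: entry only in sign-up years, exit only at contract expiry
    (non-exiting contracts renew).

    Returns ``(panel, truth)``; panel is long format, one row per parcel-year,
    with at-risk flags ``signup_next`` and ``crp_expiry_next``.
    """
    config.validate()
    rng = config.rng(STREAM_PARCELS)
    years = config.years
    n = config.n_parcels
    n_years = len(years)
    cc = config.cre_coefs
    rp = config.returns_params
    signups = set(config.signup_years().tolist())

    lrr = rng.integers(0, config.n_lrr, n)
    ef = np.exp(rng.normal(4.5, 0.5, n))  # hectares represented per point
    soil = rng.standard_normal(n)
    mu_crop = rng.normal(rp["crop_mean"], rp["crop_parcel_sd"], n)
    pasture_ret = rng.normal(rp["pasture_mean"], rp["pasture_sd"], n)
    crp_ret = rng.normal(rp["crp_mean"], rp["crp_sd"], n)
    crop_ret = mu_crop[:, None] + rng.normal(
        0.0, rp["crop_year_sd"], (n, n_years))

    # parcel effect correlated with the parcel-mean return gap (CRE device)
    zbar = (mu_crop - pasture_ret) / rp["scale"]
    alpha = cc["gamma"] * (zbar - zbar.mean()) + rng.normal(0, cc["re_sd"], n)

    def logit_p(direction: str, z: np.ndarray) -> np.ndarray:
        b = cc[direction]
        return expit(b["intercept"] + b["return"] * z + b["soil"] * soil
                     + alpha)

    # initial states
    u = rng.random(n)
    state = np.where(u < config.crp_initial_share, 2,
                     np.where(u < config.crp_initial_share
                              + config.pasture_initial_share, 1, 0))
    # 0=cropland 1=pasture 2=crp
    expiry = np.full(n, -1)
    in_crp0 = state == 2
    past_signups = years[0] - config.crp_signup_interval * rng.integers(
        0, config.crp_contract_years // config.crp_signup_interval,
        in_crp0.sum())
    expiry[in_crp0] = past_signups + config.crp_contract_years

    states = np.empty((n, n_years), dtype=np.int8)
    expiries = np.full((n, n_years), -1)
    states[:, 0] = state
    expiries[:, 0] = expiry
    for t in range(1, n_years):
        yr = years[t]
        # the t-1 -> t transition is decided on returns observed at t-1
        z_pas = (crop_ret[:, t - 1] - pasture_ret) / rp["scale"]
        z_crp = (crop_ret[:, t - 1] - crp_ret) / rp["scale"]
        new = state.copy()
        u1 = rng.random(n)
        u2 = rng.random(n)
        # pasture -> cropland
        m = state == 1
        new[m & (u1 < logit_p("pasture_to_crop", z_pas))] = 0
        # cropland -> pasture (every year) / -> crp (sign-up years only)
        m = state == 0
        to_pas = m & (u1 < logit_p("crop_to_pasture", z_pas))
        new[to_pas] = 1
        if yr in signups:
            to_crp = m & ~to_pas & (u2 < logit_p("crop_to_crp", z_crp))
            new[to_crp] = 2
            expiry[to_crp] = yr + config.crp_contract_years
        # crp -> cropland only at expiry; otherwise the contract renews
        m = state == 2
        at_expiry = m & (expiry == yr)
        exits = at_expiry & (u1 < logit_p("crp_to_crop", z_crp))
        new[exits] = 0
        expiry[exits] = -1
        renew = at_expiry & ~exits
        expiry[renew] = yr + config.crp_contract_years
        state = new
        states[:, t] = state
        expiries[:, t] = expiry

    state_labels = np.array(["cropland", "pasture", "crp"])
    next_year = np.concatenate([years[1:], [years[-1] + 1]])
    signup_next = np.isin(next_year, list(signups))
    panel = pd.DataFrame({
        "parcel_id": np.repeat(np.arange(n), n_years),
        "lrr_id": np.repeat(lrr, n_years),
        "expansion_factor_ha": np.repeat(ef, n_years),
        "year": np.tile(years, n),
        "state": state_labels[states.ravel()],
        "crop_return": crop_ret.ravel(),
        "pasture_return": np.repeat(pasture_ret, n_years),
        "crp_return": np.repeat(crp_ret, n_years),
        "soil_climate": np.repeat(soil, n_years),
        "crp_expiry_year": expiries.ravel(),
        "signup_next": np.tile(signup_next, n),
        "crp_expiry_next": (expiries == next_year[None, :]).ravel(),
    })
    truth = {
        "cre_coefs": cc,
        "returns_scale": rp["scale"],
        "alpha_sd_total": float(np.std(alpha)),
    }
    return panel, truth


# ----------------------------------------------------------------------
# nutrients, responses, carbon
# ----------------------------------------------------------------------
def gen_nutrients_and_responses(
        config: ScenarioConfig, field_panel: pd.DataFrame,
        parcel_panel: pd.DataFrame | None = None,
        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None,
                   dict[str, Any]]:
    """County nutrient totals, the environmental response table, and
    per-parcel carbon stocks.

    County totals are exact linear combinations of crop areas and the true
    per-crop rates, so the rate solver can invert them to machine precision.
    Response rates and carbon stocks are log-normal draws around the
    configured means.
    """
    config.validate()
    rng = config.rng(STREAM_NUTRIENTS)
    npar = config.nutrient_params
    areas = (field_panel.groupby(["county_id", "year", "crop"])["area_ha"]
             .sum().unstack("crop", fill_value=0.0).reset_index())
    for crop in config.crops:
        if crop not in areas:
            areas[crop] = 0.0
    n_rates = {c: npar["n_base_rate"] * npar["n_ratio"][c]
               for c in config.crops}
    p_rates = {c: npar["p_base_rate"] * npar["p_ratio"][c]
               for c in config.crops}
    total_n = sum(areas[c] * n_rates[c] for c in config.crops)
    total_p = sum(areas[c] * p_rates[c] for c in config.crops)
    county = pd.DataFrame({
        "county_id": areas["county_id"],
        "year": areas["year"],
        "total_n_mg": total_n / 1000.0,   # kg -> Mg
        "total_p_mg": total_p / 1000.0,
    })
    for crop in config.crops:
        county[f"area_{crop}_ha"] = areas[crop]

    rng_resp = config.rng(STREAM_RESPONSES)
    rp = config.response_params
    rows = []
    for block, keys in (("rotation", ROTATION_CATEGORIES), ("cover", COVERS)):
        for key in keys:
            row = {"row_type": block, "category": key}
            for col, mean in rp[block][key].items():
                row[col] = mean * float(
                    np.exp(rng_resp.normal(0.0, rp["log_sd"])))
            rows.append(row)
    responses = pd.DataFrame(rows)
    # keep the configured erodibility ordering under noise
    crop_row = responses["category"] == "cropland"
    grass_row = responses["category"] == "grassland"
    e_crop = responses.loc[crop_row, "erosion"].iloc[0]
    e_grass = responses.loc[grass_row, "erosion"].iloc[0]
    if e_grass > e_crop:
        responses.loc[grass_row, "erosion"] = e_crop

    carbon = None
    if parcel_panel is not None:
        cp = config.carbon_params
        rng_c = config.rng(STREAM_CARBON)
        ids = np.sort(parcel_panel["parcel_id"].unique())
        carbon = pd.DataFrame({
            "parcel_id": ids,
            "biomass_c": np.exp(rng_c.normal(
                cp["biomass_log_mean"], cp["biomass_log_sd"], len(ids))),
            "soc": np.exp(rng_c.normal(
                cp["soc_log_mean"], cp["soc_log_sd"], len(ids))),
        })

    truth = {"n_rates": n_rates, "p_rates": p_rates}
    return county, responses, carbon, truth


# ----------------------------------------------------------------------
# scenario writer
# ----------------------------------------------------------------------
def write_scenario(config: ScenarioConfig, outdir: str) -> dict[str, str]:
    """Generate every input and write the CSV/YAML bundle a pipeline run
    consumes.  Returns a dict of file paths."""
    os.makedirs(outdir, exist_ok=True)
    prices = gen_prices(config)
    fields, rotation_truth, strata_meta = gen_field_panel(config, prices)
    parcels, parcel_truth = gen_parcel_panel(config, prices)
    county, responses, carbon, nutrient_truth = gen_nutrients_and_responses(
        config, fields, parcels)

    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False)
        paths[name] = path

    _write("prices.csv", prices)
    _write("fields.csv", fields)
    _write("strata.csv", strata_meta)
    _write("parcels.csv", parcels)
    _write("county_nutrients.csv", county)
    _write("responses.csv", responses)
    _write("parcel_carbon.csv", carbon)

    truth = {
        "seed": int(config.seed),
        "shock_vector": [float(v) for v in config.shock_vector],
        "var_coef": [[float(v) for v in row] for row in config.var_coef],
        "rotation_coefs": rotation_truth.to_dict(orient="records"),
        "cre": parcel_truth,
        "nutrients": nutrient_truth,
    }
    tpath = os.path.join(outdir, "truth.yaml")
    with open(tpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_pyify(truth), fh, sort_keys=False)
    paths["truth.yaml"] = tpath
    config.to_yaml(os.path.join(outdir, "scenario.yaml"))
    paths["scenario.yaml"] = os.path.join(outdir, "scenario.yaml")
    return paths


def _pyify(obj):
    """Recursively convert numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
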