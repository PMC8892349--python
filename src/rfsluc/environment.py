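"""Nutrient, water-quality, and erosion accounting.

County nutrient totals plus fixed per-crop application ratios are inverted to
per-crop rates.  Rotation-probability deltas and attributed extent changes are
then converted into per-indicator changes by weighting per-hectare response
rates: rotation deltas weight the per-rotation-category rates by the change in
category probability; extent deltas weight the cropland-minus-prior-cover rate
difference by each attributed parcel's weight and area.  Everything is
assembled into a summary-table layout with BAU-relative and per-BGY
normalizations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import units

# indicator key -> (response-table column, kg -> report-unit divisor)
INDICATORS = {
    "n_applied_gg": ("n_rate", units.KG_PER_GG),
    "p_applied_gg": ("p_rate", units.KG_PER_GG),
    "nitrate_gg": ("nitrate_leach", units.KG_PER_GG),
    "p_runoff_mg": ("p_runoff", units.KG_PER_MG),
    "erosion_gg": ("erosion", units.KG_PER_GG / units.KG_PER_MG),
    # erosion rates are Mg/ha, so the divisor converts Mg -> Gg
}

INDICATOR_LABELS = {
    "n_applied_gg": "N applied (Gg-N/y)",
    "p_applied_gg": "P applied (Gg-P/y)",
    "nitrate_gg": "Nitrate leaching (Gg-N/y)",
    "p_runoff_mg": "P runoff (Mg-P/y)",
    "erosion_gg": "Soil erosion (Gg/y)",
}


def solve_crop_rates(county: pd.DataFrame, n_ratio: dict[str, float],
                     p_ratio: dict[str, float]) -> pd.DataFrame:
    """Invert county totals to per-crop application rates.

    With ratio vector k (corn normalized to 1) and areas a_c, the base rate is
    r = total / sum_c k_c a_c and the per-crop rate is r * k_c.  Totals are
    in Mg; rates come out in kg/ha.
    """
    crops = list(n_ratio)
    recs = []
    for _, row in county.iterrows():
        areas = {c: row[f"area_{c}_ha"] for c in crops}
        for total_col, ratio, rate_name in (
                ("total_n_mg", n_ratio, "n_rate"),
                ("total_p_mg", p_ratio, "p_rate")):
            denom = sum(ratio[c] * areas[c] for c in crops)
            total_kg = row[total_col] * units.KG_PER_MG
            if denom <= 0:
                if total_kg > 0:
                    raise ValueError(
                        f"county {row['county_id']} year {row['year']}: "
                        f"nonzero {total_col} with zero weighted area")
                base = 0.0
            else:
                base = total_kg / denom
            for c in crops:
                recs.append({"county_id": row["county_id"],
                             "year": row["year"], "crop": c,
                             "rate": rate_name, "kg_per_ha": base * ratio[c]})
    out = pd.DataFrame(recs)
    return (out.pivot_table(index=["county_id", "year", "crop"],
                            columns="rate", values="kg_per_ha")
            .reset_index())


def _rate_lookup(response: pd.DataFrame, row_type: str) -> pd.DataFrame:
    sub = response[response["row_type"] == row_type].set_index("category")
    return sub


def rotation_indicator_deltas(response: pd.DataFrame,
                              category_deltas: pd.DataFrame,
                              ) -> dict[str, float]:
    """Per-indicator change from rotation shifts on existing cropland.

    ``category_deltas`` has one row per stratum and rotation category with
    the stratum area (ha) and the annual-mean change in category probability;
    the contribution is sum(area * d_prob * rate).
    """
    rates = _rate_lookup(response, "rotation")
    missing = set(category_deltas["category"]) - set(rates.index)
    if missing:
        raise ValueError(f"response table lacks rotation rows {missing}")
    out = {}
    joined = category_deltas.merge(
        rates.reset_index()[["category", *{c for c, _ in
                                           INDICATORS.values()}]],
        on="category")
    base = joined["area_ha"] * joined["d_prob"]
    for key, (col, divisor) in INDICATORS.items():
        out[key] = float((base * joined[col]).sum() / divisor)
    return out


def extent_indicator_deltas(response: pd.DataFrame,
                            conversion_weights: pd.DataFrame,
                            avoided_weights: pd.DataFrame,
                            avoided_cover: str = "grassland",
                            ) -> dict[str, float]:
    """Per-indicator change from cropland-extent shifts.

    Converted parcels contribute weight x area x (cropland rate - prior-cover
    rate).  Avoided-abandonment parcels remain cropland instead of reverting
    to ``avoided_cover``, so they contribute the same difference with the
    same (positive) sign, weighted by their expected avoided probability.
    """
    rates = _rate_lookup(response, "cover")
    if "cropland" not in rates.index:
        raise ValueError("response table lacks a cropland cover row")
    out = {k: 0.0 for k in INDICATORS}

    def add(df: pd.DataFrame, cover_col) -> None:
        if df is None or len(df) == 0:
            return
        covers = df[cover_col] if cover_col in df else pd.Series(
            avoided_cover, index=df.index)
        missing = set(covers) - set(rates.index)
        if missing:
            raise ValueError(f"response table lacks cover rows {missing}")
        w = (df["weight"] * df["area_ha"]).to_numpy()
        for key, (col, divisor) in INDICATORS.items():
            diff = (rates.loc["cropland", col]
                    - rates.loc[covers, col].to_numpy())
            out[key] += float((w * diff).sum() / divisor)

    add(conversion_weights, "prior_cover")
    avoided = None
    if avoided_weights is not None and len(avoided_weights):
        avoided = avoided_weights.assign(prior_cover=avoided_cover)
    add(avoided, "prior_cover")
    return out


@dataclass
class Table1Summary:
    """Summary grid: one row per indicator, component and combined deltas
    with BAU-relative normalizations."""
    table: pd.DataFrame
    demand_increment: float

    def row(self, indicator: str) -> pd.Series:
        return self.table.set_index("indicator").loc[indicator]


def combine_and_normalize(rotation_deltas: dict[str, float],
                          extent_deltas: dict[str, float],
                          baselines: dict[str, float],
                          demand_increment: float =
                          units.DEMAND_INCREMENT_BGY,
                          extra_rows: pd.DataFrame | None = None,
                          ) -> Table1Summary:
    """Assemble the indicator summary.

    combined = rotation + extent (exact); pct_of_bau = 100*combined/baseline
    (NaN and flagged when the baseline is zero); pct_per_bgy divides by the
    ethanol-demand increment in BGY.
    """
    keys = sorted(set(rotation_deltas) | set(extent_deltas))
    recs = []
    for key in keys:
        rot = float(rotation_deltas.get(key, 0.0))
        ext = float(extent_deltas.get(key, 0.0))
        combined = rot + ext
        base = baselines.get(key)
        if base is None or base == 0:
            pct = np.nan
            flag = "zero_baseline"
        else:
            pct = 100.0 * combined / base
            flag = ""
        recs.append({
            "indicator": key,
            "rotation_delta": rot,
            "extent_delta": ext,
            "combined": combined,
            "bau_baseline": np.nan if base is None else float(base),
            "pct_of_bau": pct,
            "pct_per_bgy": pct / demand_increment,
            "flag": flag,
        })
    table = pd.DataFrame(recs)
    if extra_rows is not None:
        table = pd.concat([extra_rows, table], ignore_index=True)
    return Table1Summary(table, demand_increment)


def observed_indicator_levels(response: pd.DataFrame,
                              stratum_shares: pd.DataFrame,
                              cropland_parcels: pd.DataFrame,
                              ) -> dict[str, float]:
    """Factual-scenario indicator levels, used to derive BAU baselines as
    (factual level - combined delta).

    ``stratum_shares`` has stratum area and factual rotation-category shares
    (annual mean); ``cropland_parcels`` has expansion factors of parcels
    observed as cropland (annual mean hectares).
    """
    rot_rates = _rate_lookup(response, "rotation")
    cov_rates = _rate_lookup(response, "cover")
    out = {}
    base = stratum_shares["area_ha"] * stratum_shares["share"]
    joined_rate = rot_rates.loc[stratum_shares["category"]]
    crop_ha = float(cropland_parcels["area_ha"].sum())
    for key, (col, divisor) in INDICATORS.items():
        rot_level = float((base * joined_rate[col].to_numpy()).sum())
        ext_level = crop_ha * float(cov_rates.loc["cropland", col])
        # rotation rates already describe cropland hectares in the rotation
        # panel; the cover term adds the NRI-represented cropland outside it
        out[key] = (rot_level + ext_level) / divisor
    return out
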