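"""Nutrient-rate inversion, indicator accounting, and summary assembly."""
import numpy as np
import pandas as pd
import pytest

from rfsluc.environment import (combine_and_normalize,
                                extent_indicator_deltas,
                                rotation_indicator_deltas, solve_crop_rates)
from rfsluc.synth import gen_nutrients_and_responses

from conftest import tiny_config


def _county(total_n, total_p, corn_ha, other_ha):
    return pd.DataFrame([{"county_id": 0, "year": 2008,
                          "total_n_mg": total_n, "total_p_mg": total_p,
                          "area_corn_ha": corn_ha,
                          "area_other_ha": other_ha}])


class TestSolveCropRates:
    def test_single_crop(self):
        """100 Mg on 1000 ha of one crop is 100 kg/ha."""
        rates = solve_crop_rates(_county(100.0, 10.0, 1000.0, 0.0),
                                 {"corn": 1.0, "other": 0.4},
                                 {"corn": 1.0, "other": 0.6})
        corn = rates[rates["crop"] == "corn"].iloc[0]
        assert corn["n_rate"] == pytest.approx(100.0)

    def test_two_crop_hand_solution(self):
        """1000 ha corn (k=1) + 1000 ha at k=0.5 with 150 Mg total:
        corn 100 kg/ha, the other crop 50 kg/ha."""
        rates = solve_crop_rates(_county(150.0, 150.0, 1000.0, 1000.0),
                                 {"corn": 1.0, "other": 0.5},
                                 {"corn": 1.0, "other": 0.5})
        r = rates.set_index("crop")
        assert r.loc["corn", "n_rate"] == pytest.approx(100.0)
        assert r.loc["other", "n_rate"] == pytest.approx(50.0)

    def test_round_trip_against_generator_truth(self, small_config,
                                                small_scenario):
        """Exact linear inversion: solved rates match the generating rates
        to 1e-10 relative error."""
        county, _, _, truth = gen_nutrients_and_responses(
            small_config, small_scenario["fields"])
        np_ = small_config.nutrient_params
        rates = solve_crop_rates(county.head(20), np_["n_ratio"],
                                 np_["p_ratio"])
        for crop, want in truth["n_rates"].items():
            got = rates[rates["crop"] == crop]["n_rate"]
            sel = got[np.isfinite(got)]
            np.testing.assert_allclose(sel, want, rtol=1e-10)

    def test_zero_area_nonzero_total_rejected(self):
        with pytest.raises(ValueError, match="zero weighted area"):
            solve_crop_rates(_county(10.0, 1.0, 0.0, 0.0),
                             {"corn": 1.0, "other": 0.4},
                             {"corn": 1.0, "other": 0.6})


@pytest.fixture()
def response():
    rows = []
    for cat, n, p, nit, pr, er in (
            ("continuous_corn", 180, 28, 30, 1.2, 9),
            ("corn_other", 95, 22, 20, 1.0, 7),
            ("continuous_other", 60, 18, 10, 0.8, 5)):
        rows.append({"row_type": "rotation", "category": cat, "n_rate": n,
                     "p_rate": p, "nitrate_leach": nit, "p_runoff": pr,
                     "erosion": er})
    for cat, n, p, nit, pr, er in (
            ("cropland", 120, 22, 25, 1.0, 8),
            ("pasture", 10, 2, 4, 0.3, 1.5),
            ("grassland", 0.5, 0.1, 2, 0.1, 1.0)):
        rows.append({"row_type": "cover", "category": cat, "n_rate": n,
                     "p_rate": p, "nitrate_leach": nit, "p_runoff": pr,
                     "erosion": er})
    return pd.DataFrame(rows)


class TestRotationIndicators:
    def _cat(self, d_cc, d_oth, area=100.0):
        return pd.DataFrame({
            "stratum_id": [0, 0, 0], "area_ha": area,
            "category": ["continuous_corn", "corn_other",
                         "continuous_other"],
            "d_prob": [d_cc, 0.0, d_oth]})

    def test_zero_probability_change(self, response):
        out = rotation_indicator_deltas(response, self._cat(0.0, 0.0))
        assert all(v == 0.0 for v in out.values())

    def test_hand_arithmetic(self, response):
        """100 ha, +0.1 continuous corn balanced by -0.1 continuous other,
        nitrate 30 vs 10 kg/ha: 100 x 0.1 x 20 = 200 kg N/y."""
        out = rotation_indicator_deltas(response, self._cat(0.1, -0.1))
        assert out["nitrate_gg"] == pytest.approx(200.0 / 1e6)

    def test_linearity_in_probability(self, response):
        d1 = rotation_indicator_deltas(response, self._cat(0.05, -0.02))
        d2 = rotation_indicator_deltas(response, self._cat(0.10, -0.04))
        for k in d1:
            assert d2[k] == pytest.approx(2 * d1[k], rel=1e-12)

    def test_missing_category_rejected(self, response):
        broken = response[response["category"] != "corn_other"]
        with pytest.raises(ValueError, match="corn_other"):
            rotation_indicator_deltas(broken, self._cat(0.1, -0.1))


class TestExtentIndicators:
    def _conv(self, weight, area=10.0, cover="grassland"):
        return pd.DataFrame([{"parcel_id": 0, "lrr_id": 0, "area_ha": area,
                              "prior_cover": cover, "weight": weight}])

    def test_zero_weights(self, response):
        out = extent_indicator_deltas(response, self._conv(0.0), None)
        assert all(v == 0.0 for v in out.values())

    def test_hand_arithmetic(self, response):
        """10 ha at weight 0.5, erosion 8 vs 1 Mg/ha/y: 35 Mg/y."""
        out = extent_indicator_deltas(response, self._conv(0.5), None)
        assert out["erosion_gg"] == pytest.approx(35.0 / 1000.0)

    def test_equal_rates_cancel(self, response):
        r = response.copy()
        crop_row = r[(r["row_type"] == "cover")
                     & (r["category"] == "cropland")].iloc[0]
        for col in ("n_rate", "p_rate", "nitrate_leach", "p_runoff",
                    "erosion"):
            r.loc[(r["row_type"] == "cover")
                  & (r["category"] == "grassland"), col] = crop_row[col]
        out = extent_indicator_deltas(r, self._conv(0.7), None)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_avoided_parcels_same_sign(self, response):
        avoided = pd.DataFrame([{"parcel_id": 1, "lrr_id": 0,
                                 "area_ha": 10.0, "weight": 0.5}])
        only_avoided = extent_indicator_deltas(
            response, self._conv(0.0), avoided)
        only_conv = extent_indicator_deltas(
            response, self._conv(0.5), None)
        for k in only_avoided:
            assert only_avoided[k] == pytest.approx(only_conv[k])


class TestCombine:
    def test_additivity_and_pct(self):
        """Combined equals rotation plus extent exactly; percentages follow
        the published normalization (87.1 + 47.9 = 135.0 Gg-N, 5.3% of a
        2535.5 Gg-N baseline)."""
        s = combine_and_normalize({"nitrate_gg": 87.1},
                                  {"nitrate_gg": 47.9},
                                  {"nitrate_gg": 2535.5},
                                  demand_increment=5.5)
        row = s.row("nitrate_gg")
        assert row["combined"] == pytest.approx(135.0)
        assert row["combined"] == row["rotation_delta"] + row["extent_delta"]
        assert round(row["pct_of_bau"], 1) == 5.3
        assert row["pct_per_bgy"] == pytest.approx(row["pct_of_bau"] / 5.5)

    def test_zero_deltas_zero_percent(self):
        s = combine_and_normalize({"nitrate_gg": 0.0}, {"nitrate_gg": 0.0},
                                  {"nitrate_gg": 100.0})
        assert s.row("nitrate_gg")["pct_of_bau"] == 0.0

    def test_zero_baseline_flagged(self):
        s = combine_and_normalize({"x": 1.0}, {"x": 2.0}, {"x": 0.0})
        row = s.row("x")
        assert np.isnan(row["pct_of_bau"])
        assert row["flag"] == "zero_baseline"
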