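"""Rotation model: eligibility screens, stationary rotation shares,
transition-model fitting, and counterfactual area deltas."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from rfsluc.rotation import (EligibilityCriteria, RotationTransitionModel,
                             delta_areas_from_coefs, filter_fields,
                             fit_transitions, rotation_distribution)
from rfsluc.synth import gen_field_panel, gen_prices, price_log_ratio

from conftest import tiny_config


def _toy_panel():
    """10 fields x 2 years in 3 strata; 3 fields each violate exactly one
    eligibility criterion."""
    # stratum 1 fails the cropland share screen, stratum 2 the priced share
    areas = [10.0] * 7 + [5.0, 12.0, 11.0]
    strata = [0] * 8 + [1, 2]
    rows = []
    for fid, (a, s) in enumerate(zip(areas, strata)):
        for year in (2000, 2001):
            rows.append({"field_id": fid, "stratum_id": s, "area_ha": a,
                         "year": year,
                         "crop": "corn" if fid % 2 == 0 else "other"})
    panel = pd.DataFrame(rows)
    meta = pd.DataFrame({
        "stratum_id": [0, 1, 2],
        "region_cropland_share": [0.5, 0.1, 0.5],   # stratum 1 fails
        "priced_share_of_noncorn": [0.8, 0.8, 0.3],  # stratum 2 fails
    })
    return panel, meta


class TestFilter:
    def test_toy_exclusions(self):
        """Three fields each violating one criterion leave seven."""
        panel, meta = _toy_panel()
        eligible, tally = filter_fields(panel, EligibilityCriteria(), meta)
        assert tally["n_fields"] == 10
        assert tally["n_retained"] == 7
        assert eligible["field_id"].nunique() == 7
        assert 7 not in eligible["field_id"].values  # 5-ha field excluded

    def test_zero_criteria_keep_everything(self):
        panel, meta = _toy_panel()
        crit = EligibilityCriteria(0.0, 0.0, 0.0, 0.0)
        eligible, tally = filter_fields(panel, crit, meta)
        assert tally["n_retained"] == 10
        assert 0.0 <= tally["area_share_retained"] <= 1.0

    def test_share_bounds_validated(self):
        with pytest.raises(ValueError):
            EligibilityCriteria(min_region_cropland_share=1.5)


class TestRotationDistribution:
    def test_symmetric(self):
        d = rotation_distribution(0.5, 0.5)
        assert d.pi_corn == pytest.approx(0.5)

    def test_strict_alternation(self):
        d = rotation_distribution(0.0, 1.0)
        assert d.shares["corn_other"] == pytest.approx(1.0)
        assert d.shares["continuous_corn"] == 0.0
        assert d.shares["continuous_other"] == 0.0

    def test_known_pair(self):
        """p_cc=0.7, p_oc=0.3: pi=0.5 and continuous-corn share 0.35
        (frozen from a brute-force chain simulation; see the acceptance
        suite for the simulation-based comparison)."""
        d = rotation_distribution(0.7, 0.3)
        assert d.pi_corn == pytest.approx(0.5)
        assert d.shares["continuous_corn"] == pytest.approx(0.35)

    def test_two_absorbing_states_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            rotation_distribution(1.0, 0.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_shares_sum_to_one_and_corn_consistency(self, p_cc, p_oc):
        d = rotation_distribution(p_cc, p_oc)
        assert sum(d.shares.values()) == pytest.approx(1.0)
        assert (d.shares["continuous_corn"]
                + (d.pi_corn - d.shares["continuous_corn"])
                ) == pytest.approx(d.pi_corn)

    def test_pi_increases_with_corn_price_when_coef_positive(self):
        b0_cc, b1_cc, b0_oc, b1_oc = 0.2, 1.5, -0.8, 1.2
        pis = [rotation_distribution(
            float(expit(b0_cc + b1_cc * x)),
            float(expit(b0_oc + b1_oc * x))).pi_corn
            for x in np.linspace(-1, 1, 9)]
        assert np.all(np.diff(pis) > 0)


class TestFitTransitions:
    def test_recovery_within_3se(self):
        cfg = tiny_config(n_fields=20_000, n_strata=2, seed=21)
        prices = gen_prices(cfg)
        panel, truth, _ = gen_field_panel(cfg, prices)
        model = fit_transitions(panel, prices)
        est = model.coefs_.set_index("stratum_id")
        tru = truth.set_index("stratum_id")
        for s in est.index:
            for cond in ("cc", "oc"):
                V = model.cov_[(int(s), cond)]
                se = np.sqrt(np.diag(V))
                diff = np.array([est.loc[s, f"b0_{cond}"]
                                 - tru.loc[s, f"b0_{cond}"],
                                 est.loc[s, f"b1_{cond}"]
                                 - tru.loc[s, f"b1_{cond}"]])
                assert np.all(np.abs(diff) < 3 * se)

    def test_mean_fitted_probability_equals_frequency(self):
        """The logistic score equation forces the average fitted
        probability to equal the empirical transition frequency."""
        cfg = tiny_config(n_fields=3000, n_strata=1, seed=23)
        prices = gen_prices(cfg)
        panel, _, _ = gen_field_panel(cfg, prices)
        model = fit_transitions(panel, prices)
        x = price_log_ratio(prices, "observed")
        trans = RotationTransitionModel._transitions(panel, x)
        sub = trans[trans["prev_corn"]]
        c = model.coefs_.iloc[0]
        fitted = expit(c["b0_cc"] + c["b1_cc"] * sub["x"])
        assert fitted.mean() == pytest.approx(sub["corn"].mean(), abs=1e-6)

    def test_separation_flagged_with_pooled_fallback(self):
        cfg = tiny_config(n_fields=2000, n_strata=2, seed=25)
        prices = gen_prices(cfg)
        panel, _, _ = gen_field_panel(cfg, prices)
        # force stratum 1's corn-after-corn cell to a single outcome
        mask = panel["stratum_id"] == 1
        panel.loc[mask, "crop"] = "corn"
        model = fit_transitions(panel, prices)
        assert (1, "cc") in model.separation_flags_
        assert np.isfinite(
            model.coefs_.set_index("stratum_id").loc[1]).all()


@pytest.fixture(scope="module")
def setup():
    coefs = pd.DataFrame({"stratum_id": [0], "b0_cc": [0.2],
                          "b1_cc": [1.5], "b0_oc": [-0.8],
                          "b1_oc": [1.2]})
    panel = pd.DataFrame({"field_id": [0], "stratum_id": [0],
                          "area_ha": [100.0], "year": [2008],
                          "crop": ["corn"]})
    years = np.arange(2008, 2012)
    x_rfs = pd.Series(0.3, index=years)
    x_bau = pd.Series(0.1, index=years)
    return coefs, panel, x_rfs, x_bau, years


class TestDeltaAreas:
    def test_equal_prices_zero_delta(self, setup):
        coefs, panel, x_rfs, _, years = setup
        d = delta_areas_from_coefs(coefs, panel, x_rfs, x_rfs, years)
        assert d.corn_mha_per_y == 0.0
        assert (d.category_deltas["d_prob"] == 0.0).all()

    def test_single_field_closed_form(self, setup):
        """Area delta equals field area times the stationary-share change
        computed independently via rotation_distribution."""
        coefs, panel, x_rfs, x_bau, years = setup
        c = coefs.iloc[0]

        def pi(x):
            return rotation_distribution(
                float(expit(c.b0_cc + c.b1_cc * x)),
                float(expit(c.b0_oc + c.b1_oc * x))).pi_corn

        expected = 100.0 * (pi(0.3) - pi(0.1)) / 1e6
        d = delta_areas_from_coefs(coefs, panel, x_rfs, x_bau, years)
        assert d.corn_mha_per_y == pytest.approx(expected, rel=1e-12)
        assert (d.continuous_corn_mha + d.rotated_corn_mha
                == pytest.approx(d.corn_mha_per_y, rel=1e-12))

    def test_area_linearity(self, setup):
        coefs, panel, x_rfs, x_bau, years = setup
        d1 = delta_areas_from_coefs(coefs, panel, x_rfs, x_bau, years)
        doubled = panel.assign(area_ha=panel["area_ha"] * 2)
        d2 = delta_areas_from_coefs(coefs, doubled, x_rfs, x_bau, years)
        assert d2.corn_mha_per_y == pytest.approx(2 * d1.corn_mha_per_y)

    def test_missing_stratum_fit_named(self, setup):
        coefs, panel, x_rfs, x_bau, years = setup
        other = panel.assign(stratum_id=5)
        with pytest.raises(ValueError, match="5"):
            delta_areas_from_coefs(coefs, other, x_rfs, x_bau, years)
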