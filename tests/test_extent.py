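"""Extensive margin: at-risk construction, CRE estimation, counterfactual
deltas, and attribution of observed conversions."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rfsluc.extent import (CRETransitionModel, attribute, fit_cre,
                           net_cropland_change, observed_conversions,
                           predict_delta)
from rfsluc.synth import gen_parcel_panel

from conftest import tiny_config


@pytest.fixture(scope="module")
def fitted():
    cfg = tiny_config(n_parcels=8000, n_lrr=3, seed=31)
    panel, truth = gen_parcel_panel(cfg)
    model = fit_cre(panel, returns_scale=cfg.returns_params["scale"])
    return cfg, panel, truth, model


class TestAtRisk:
    def test_crp_exit_rows_only_at_expiry(self, fitted):
        _, panel, _, model = fitted
        risk = model.at_risk_["crp_to_crop"]
        merged = risk.merge(panel, left_on=["parcel_id", "year"],
                            right_on=["parcel_id", "year"])
        assert merged["crp_expiry_next"].all()

    def test_crp_entry_rows_only_at_signups(self, fitted):
        _, panel, _, model = fitted
        risk = model.at_risk_["crop_to_crp"]
        merged = risk.merge(panel, on=["parcel_id", "year"])
        assert merged["signup_next"].all()


class TestFit:
    def test_recovery_within_3se(self, fitted):
        """Inverse-variance pooled CRE returns coefficient matches the
        generating coefficient within 3 SE for each direction."""
        cfg, _, _, model = fitted
        for direction in ("pasture_to_crop", "crop_to_pasture"):
            true_b = cfg.cre_coefs[direction]["return"]
            est, var = [], []
            for (d, lrr), beta in model.params_.items():
                if d != direction or (d, lrr) in model.flags_:
                    continue
                est.append(beta[1])
                var.append(model.cov_[(d, lrr)][1, 1])
            w = 1.0 / np.asarray(var)
            pooled = float(np.sum(w * est) / w.sum())
            se = float(np.sqrt(1.0 / w.sum()))
            assert abs(pooled - true_b) < 3 * se

    def test_constant_returns_unidentified_flagged(self):
        cfg = tiny_config(n_parcels=1500, n_lrr=2, seed=33)
        panel, _ = gen_parcel_panel(cfg)
        panel["crop_return"] = 250.0
        panel["pasture_return"] = 100.0
        panel["crp_return"] = 120.0
        with pytest.warns(UserWarning, match="unidentified"):
            CRETransitionModel().fit(panel)


class TestPredictDelta:
    def test_zero_impact_zero_delta(self, fitted):
        _, _, _, model = fitted
        delta = predict_delta(model, 0.0, np.arange(2008, 2016))
        assert delta.d_conversion_ha == 0.0
        assert delta.d_abandonment_ha == 0.0

    def test_positive_impact_signs(self, fitted):
        """Higher factual crop returns mean more conversion and less
        abandonment than BAU."""
        _, _, _, model = fitted
        delta = predict_delta(model, 30.0, np.arange(2008, 2016))
        assert delta.d_conversion_ha > 0
        assert delta.d_abandonment_ha < 0
        assert delta.avoided_abandonment_ha > 0

    def test_monotone_in_impact(self, fitted):
        _, _, _, model = fitted
        years = np.arange(2008, 2016)
        d10 = predict_delta(model, 10.0, years)
        d30 = predict_delta(model, 30.0, years)
        assert d30.d_conversion_ha >= d10.d_conversion_ha
        assert (d30.avoided_abandonment_ha
                >= d10.avoided_abandonment_ha)

    def test_single_parcel_closed_form(self, fitted):
        """Delta equals ef x (p_rfs - p_bau) with probabilities recomputed
        independently from the stored coefficients."""
        _, _, _, model = fitted
        direction, years = "pasture_to_crop", [2010]
        risk = model.at_risk_[direction]
        row = risk[risk["year"] == 2010].iloc[0]
        key = (direction, int(row["lrr_id"]))
        beta = model.params_[key]
        eta = (beta[0] + beta[1] * row["z"] + beta[2] * row["soil"]
               + beta[3] * row["zbar"])
        z_bau = (row["crop_return"] / 1.3 - row["alt_return"]) / 100.0
        eta_b = (beta[0] + beta[1] * z_bau + beta[2] * row["soil"]
                 + beta[3] * row["zbar"])
        expected = row["ef"] * (expit(eta) - expit(eta_b))
        # isolate the parcel: restrict the at-risk set to this single row
        model2 = CRETransitionModel(returns_scale=100.0)
        model2.params_ = {key: beta}
        model2.at_risk_ = {d: (risk.loc[[row.name]] if d == direction
                               else model.at_risk_[d].iloc[0:0])
                           for d in model.at_risk_}
        delta = model2.predict_delta(30.0, years)
        assert delta.d_conversion_ha == pytest.approx(expected, rel=1e-10)

    def test_years_outside_panel_rejected(self, fitted):
        _, _, _, model = fitted
        with pytest.raises(ValueError, match="outside"):
            predict_delta(model, 30.0, [2050])

    def test_avoided_weights_sum_to_avoided_hectares(self, fitted):
        _, _, _, model = fitted
        years = np.arange(2008, 2016)
        delta = predict_delta(model, 30.0, years)
        avoided = model.avoided_abandonment_weights(30.0, years)
        total = float((avoided["weight"] * avoided["area_ha"]).sum())
        assert total == pytest.approx(delta.avoided_abandonment_ha,
                                      rel=1e-9)


class TestAttribution:
    def _delta(self, by_lrr):
        rows = [{"lrr_id": l, "year": 2010, "conv_rfs": 0, "conv_bau": 0,
                 "aband_rfs": 0, "aband_bau": 0, "d_conv_ha": v,
                 "d_aband_ha": 0.0} for l, v in by_lrr.items()]
        from rfsluc.extent import TransitionDelta
        return TransitionDelta(pd.DataFrame(rows))

    def _observed(self, by_lrr):
        rows = []
        for l, areas in by_lrr.items():
            for i, a in enumerate(areas):
                rows.append({"parcel_id": 100 * l + i, "lrr_id": l,
                             "area_ha": a, "year": 2011,
                             "prior_cover": "pasture"})
        return pd.DataFrame(rows)

    def test_full_attribution(self):
        attr = attribute(self._delta({0: 200.0}),
                         self._observed({0: [120.0, 80.0]}))
        assert (attr.weights["weight"] == 1.0).all()

    def test_fractional_attribution(self):
        attr = attribute(self._delta({0: 50.0}),
                         self._observed({0: [100.0, 100.0]}))
        assert np.allclose(attr.weights["weight"], 0.25)

    def test_area_conservation_random_scenario(self):
        """Attributed area equals min(predicted, observed) in every LRR."""
        rng = np.random.default_rng(4)
        deltas = {l: float(rng.uniform(0, 400)) for l in range(5)}
        obs = {l: rng.uniform(10, 120, rng.integers(1, 6)).tolist()
               for l in range(5)}
        attr = attribute(self._delta(deltas), self._observed(obs))
        for l in range(5):
            w = attr.weights[attr.weights["lrr_id"] == l]
            got = float((w["weight"] * w["area_ha"]).sum())
            assert got == pytest.approx(min(deltas[l], sum(obs[l])))
            assert ((w["weight"] >= 0) & (w["weight"] <= 1)).all()

    def test_nothing_observed_warns(self):
        with pytest.warns(UserWarning, match="nothing to attribute"):
            attr = attribute(self._delta({0: 50.0, 1: 10.0}),
                             self._observed({1: [30.0]}))
        f = attr.fractions.set_index("lrr_id")
        assert f.loc[0, "fraction"] == 0.0


class TestNetChange:
    def test_components_and_signs(self):
        from rfsluc.extent import TransitionDelta
        t = pd.DataFrame([{"lrr_id": 0, "year": 2010, "conv_rfs": 0,
                           "conv_bau": 0, "aband_rfs": 0, "aband_bau": 0,
                           "d_conv_ha": 1.8e6, "d_aband_ha": -0.4e6}])
        net = net_cropland_change(TransitionDelta(t))
        assert net["net_mha"] == pytest.approx(2.2)
        # extra abandonment (positive d_aband) reduces the net change
        t2 = t.assign(d_aband_ha=0.4e6)
        net2 = net_cropland_change(TransitionDelta(t2))
        assert net2["net_mha"] == pytest.approx(1.4)

    def test_zero(self):
        from rfsluc.extent import TransitionDelta
        t = pd.DataFrame([{"lrr_id": 0, "year": 2010, "conv_rfs": 0,
                           "conv_bau": 0, "aband_rfs": 0, "aband_bau": 0,
                           "d_conv_ha": 0.0, "d_aband_ha": 0.0}])
        assert net_cropland_change(TransitionDelta(t))["net_mha"] == 0.0


def test_observed_conversions_prior_cover(fitted):
    _, panel, _, _ = fitted
    obs = observed_conversions(panel, np.arange(2008, 2016))
    assert set(obs["prior_cover"]) <= {"pasture", "grassland"}
    assert (obs["area_ha"] > 0).all()
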