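import pandas as pd
import pytest

from rfsluc.config import ScenarioConfig
from rfsluc.pipeline import run_pipeline
from rfsluc.synth import gen_field_panel, gen_parcel_panel, gen_prices


def tiny_config(**overrides) -> ScenarioConfig:
    base = dict(n_fields=800, n_parcels=600, n_strata=3, n_lrr=4,
                n_counties=5, seed=7)
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def small_scenario(small_config):
    prices = gen_prices(small_config)
    fields, rotation_truth, strata = gen_field_panel(small_config, prices)
    parcels, parcel_truth = gen_parcel_panel(small_config, prices)
    return {"prices": prices, "fields": fields,
            "rotation_truth": rotation_truth, "strata": strata,
            "parcels": parcels, "parcel_truth": parcel_truth}


@pytest.fixture(scope="session")
def small_pipeline():
    return run_pipeline(tiny_config(n_fields=1500, n_parcels=1200))


@pytest.fixture(scope="session")
def zero_shock_pipeline():
    return run_pipeline(tiny_config(shock_vector=[0.0, 0.0]))
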