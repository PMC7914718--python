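import dataclasses

import numpy as np
import pytest

from cardiomech import ModelParams
from cardiomech.engine import ScenarioConfig, clear_ecm_cache, get_ecm_model


@pytest.fixture(scope="session")
def params():
    return ModelParams().validate()


@pytest.fixture(scope="session")
def small_params():
    """Reduced culture box for fast FEM/engine tests: same physics, same
    40 um elements, 6x4x4 grid."""
    return ModelParams(domain=(240.0, 160.0, 160.0), n_cells=12).validate()


@pytest.fixture(scope="session")
def small_ecm(small_params):
    cfg = ScenarioConfig.preset("DIFF", params=small_params)
    return get_ecm_model(cfg.params)


@pytest.fixture(scope="session")
def small_diff_config(small_params):
    return ScenarioConfig.preset("DIFF", params=small_params)


def make_params(**over):
    return dataclasses.replace(ModelParams(), **over).validate()
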