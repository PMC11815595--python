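import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import violakin as vk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ms_params() -> vk.KineticParameters:
    """Published Monod-sucrose / sigmoid-nitrate batch fit."""
    return vk.BATCH_FIT_MONOD_SIGMOID


@pytest.fixture(scope="session")
def ms_model() -> vk.ModelType:
    return vk.ModelType.MONOD_SIGMOID


@pytest.fixture(scope="session")
def batch_init() -> vk.CultureState:
    """Optimized batch medium with the standard inoculum."""
    return vk.CultureState(x=7.0, s1=45.6, s2=2.1, v=1.2)


@pytest.fixture(scope="session")
def paper_feed() -> vk.FeedStrategy:
    """The experimentally validated fed-batch strategy."""
    return vk.FeedStrategy(
        v0=1.2, t_feed_start=10.0, t_end=17.0, flow=0.072,
        feed_s1=250.0, feed_s2=15.0,
    )


@pytest.fixture(scope="session")
def clean_dataset(ms_params, ms_model, batch_init) -> vk.TimeCourseDataset:
    """Noise-free daily triplicate batch dataset from the published fit."""
    spec = vk.SyntheticSpec(
        true_params=ms_params, model_type=ms_model, seed=123,
        init=batch_init, noise_cv=0.0,
    )
    return vk.generate_batch_dataset(spec)


def single_point_dataset(value: float, predicted_time: float = 1.0):
    """One biomass measurement (helper for objective-definition tests)."""
    return pd.DataFrame(
        {
            "time_d": [0.0, predicted_time],
            "species": ["biomass", "biomass"],
            "replicate": [1, 1],
            "value": [7.0, value],
        }
    )
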