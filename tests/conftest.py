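import dataclasses

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import oligocea as oc

hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config() -> oc.ModelConfig:
    return oc.builtin_base_case()


@pytest.fixture(scope="session")
def lifetable() -> oc.LifeTable:
    return oc.default_lifetable()


@pytest.fixture(scope="session")
def base_outcomes(base_config, lifetable):
    return oc.run_all(base_config, lifetable)


@pytest.fixture
def zero_lifetable() -> oc.LifeTable:
    """An immortal-background cohort: qx = 0 at every age 0-100."""
    return oc.LifeTable(age_min=0, qx=np.zeros(101))


def constant_lifetable(q: float) -> oc.LifeTable:
    return oc.LifeTable(age_min=0, qx=np.full(101, q))


def with_settings(config: oc.ModelConfig, **kwargs) -> oc.ModelConfig:
    return dataclasses.replace(
        config, settings=dataclasses.replace(config.settings, **kwargs))


def with_strategy(strategy: oc.StrategyParams, **kwargs) -> oc.StrategyParams:
    return dataclasses.replace(strategy, **kwargs)
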