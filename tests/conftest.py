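import numpy as np
import pytest

from plasmogamy import (Environment, EnvironmentSchedule, Genotype,
                        ModelParams, MutationParams, SurvivalModel)


@pytest.fixture
def vance() -> SurvivalModel:
    return SurvivalModel(family="vance")


@pytest.fixture
def benign() -> Environment:
    return Environment(0.5, "env1")


@pytest.fixture
def harsh() -> Environment:
    return Environment(2.2, "env2")


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams(E=100.0, T=1.0, C=0.0)


@pytest.fixture
def default_mutation() -> MutationParams:
    return MutationParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
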