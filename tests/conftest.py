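import numpy as np
import pytest

from emaxfit import DrugEffect, GrowthParameters, NoiseModel
from emaxfit.synth import design_preset, generate_growth_dataset

#: Generating truth used across recovery tests.
TRUTH = dict(lambda_=0.6, K=6.0e4, N0=1000.0, Emax=0.8, IC50=2e-3)


@pytest.fixture(scope="session")
def truth_params() -> GrowthParameters:
    return GrowthParameters(TRUTH["lambda_"], TRUTH["K"], TRUTH["N0"])


@pytest.fixture(scope="session")
def truth_effect() -> DrugEffect:
    return DrugEffect(TRUTH["Emax"], TRUTH["IC50"])


@pytest.fixture(scope="session")
def growth_template():
    return design_preset("paper-growth")


@pytest.fixture(scope="session")
def mtt_template():
    return design_preset("paper-mtt")


@pytest.fixture(scope="session")
def noiseless_dataset(truth_params, truth_effect, growth_template):
    return generate_growth_dataset(
        truth_params, truth_effect, growth_template, NoiseModel(sigma=0.0), seed=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
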