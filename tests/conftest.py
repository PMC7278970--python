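import pytest

from dsbsurv import LethalityParams, NucleusModel, OxygenModel, ScavengerModel


@pytest.fixture
def nucleus():
    return NucleusModel()


@pytest.fixture
def cho_lethality():
    # fitted CHO values: isolated-lesion and complex-lesion kill probabilities
    return LethalityParams(k_idsb=5.56e-3, k_cdsb=0.765)


@pytest.fixture
def scavenger():
    return ScavengerModel()


@pytest.fixture
def oxygen_model():
    return OxygenModel()
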