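import pytest
from hypothesis import settings

from colonsim.fixtures_io import load_dataset
from colonsim.params import DerivationContext
from colonsim.physiology import build_physiology

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dataset():
    return load_dataset()


@pytest.fixture(scope="session")
def area_physiology():
    return build_physiology("area_based")


@pytest.fixture(scope="session")
def geometry_physiology():
    return build_physiology("geometry_based")


@pytest.fixture(scope="session")
def context():
    return DerivationContext()


@pytest.fixture(scope="session")
def open_model_rows(dataset):
    """Open-model simulation of every packaged colon arm (with references)."""
    from colonsim.pipeline import RunConfig, simulate_arm

    cfg = RunConfig()
    return {
        (arm.drug_name, arm.formulation): simulate_arm(dataset, arm, cfg)
        for arm in dataset.arms
        if arm.route == "colon"
    }
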