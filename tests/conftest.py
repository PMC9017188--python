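import pytest

from motifboost.motifs import load_models, models_by_name


@pytest.fixture(scope="session")
def models():
    return load_models()


@pytest.fixture(scope="session")
def model_map(models):
    return models_by_name(models)


@pytest.fixture(scope="session")
def ck2_study():
    """Planted-substrate CK2 inhibitor study shared by recovery tests."""
    from motifboost.studies import ck2_substrate_study

    return ck2_substrate_study(seed=20260)
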