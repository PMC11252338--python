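import pytest

from triazine_qsar import DESCRIPTOR_NAMES, fit_ols, load_study_data


@pytest.fixture(scope="session")
def study_data():
    """The packaged study dataset (27 train + 5 test) and 28 designed candidates."""
    return load_study_data()


@pytest.fixture(scope="session")
def study_dataset(study_data):
    return study_data[0]


@pytest.fixture(scope="session")
def study_candidates(study_data):
    return study_data[1]


@pytest.fixture(scope="session")
def study_model(study_dataset):
    """OLS refit of pIC50 on the five study descriptors, training rows only."""
    model, _ = fit_ols(study_dataset, DESCRIPTOR_NAMES)
    return model
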