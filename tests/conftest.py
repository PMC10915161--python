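import pytest

from hydrotwin import FIXTURE_IDS, DEFAULT_CONSTANTS, load_fixture


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def cyclist1():
    """The first published cyclist twin (the paper's worked example)."""
    return load_fixture("cyclist_1")


@pytest.fixture(scope="session")
def twin1(cyclist1):
    return cyclist1.twin


@pytest.fixture(scope="session", params=FIXTURE_IDS)
def each_fixture(request):
    """Iterate over all four published twins."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # cyclist 2's beta > 1 warns by design
        return load_fixture(request.param)
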