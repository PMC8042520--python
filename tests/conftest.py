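import pytest

from crcscreen import canonical_schedules, default_parameters, with_calibrated_q


@pytest.fixture(scope="session")
def params():
    """Published base-case parameter set (q not yet calibrated)."""
    return default_parameters()


@pytest.fixture(scope="session")
def calibrated_params(params):
    """Base-case parameters with q calibrated to the published baseline."""
    return with_calibrated_q(params)


@pytest.fixture(scope="session")
def schedules():
    """The five published uptake schedules."""
    return canonical_schedules()
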