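import pytest

from monarchdd import calibrate_two_point


@pytest.fixture(scope="session")
def paper_curve():
    """Survival curve calibrated to the published endpoint survival rates:
    73.4% density-independent survival and 50.8% at 5 eggs/plant."""
    return calibrate_two_point(0.734, 0.508, 5.0)
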