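import pytest
from hypothesis import settings

from magnetodose import IronTimeSeries, ParticleSpec

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def default_spec():
    return ParticleSpec()


@pytest.fixture
def nerve_series():
    """The measured nerve iron series: days 1/3/7/14 after injection."""
    return IronTimeSeries((1.0, 3.0, 7.0, 14.0), (3.57, 2.13, 1.40, 0.34),
                          label="nerve")
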