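import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mitochimera import Genome, random_genome


@pytest.fixture
def toy_genome():
    """400 bp seeded random circular genome."""
    return random_genome(400, seed=101)


@pytest.fixture
def monomorphic_chimeric_genome():
    """30 ATG tricodons + 30 ATGA tetracodons + 30 ATG tricodons: the
    k=1 window at (+, 0) translates to 90 methionines with no stops."""
    return Genome(id="mono", seq="ATG" * 30 + "ATGA" * 30 + "ATG" * 30)
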