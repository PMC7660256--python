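import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regulonscan import DegeneratePalindrome, GeneFeature, GenomeAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def box():
    return DegeneratePalindrome()


@pytest.fixture
def two_gene_annotation():
    """Genes (100-400, +) and (600-900, -) on a 1 kb genome."""
    return GenomeAnnotation(
        genome_length=1000,
        features=(
            GeneFeature(id="g1", start=100, end=400, strand="+"),
            GeneFeature(id="g2", start=600, end=900, strand="-"),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20200925)
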