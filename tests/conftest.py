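import numpy as np
import pytest

from ubmzt.genome_model import Chromosome, GeneRecord, GenomeAnnotation
from ubmzt.synthetic_data import simulate_study


@pytest.fixture
def toy_ann() -> GenomeAnnotation:
    """A hand-built annotation on one 100 kb chromosome."""
    ann = GenomeAnnotation([Chromosome("chr1", 100_000)])
    ann.add_gene(GeneRecord("gA", "chr1", "+", 10_000, 14_000))
    ann.add_gene(GeneRecord("gB", "chr1", "-", 30_000, 36_000))
    ann.add_gene(GeneRecord("gC", "chr1", "+", 60_000, 70_000))
    return ann


@pytest.fixture(scope="session")
def default_study():
    """The default planted study (annotation, truth, read sets, FPKM).

    Session-scoped because generating ~7M reads takes a few seconds and
    several test modules only read from it.
    """
    return simulate_study(seed=11)
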