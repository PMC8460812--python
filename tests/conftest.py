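import numpy as np
import pytest

from normcov import (
    GenomeModel,
    PopulationModel,
    Replicon,
    random_replicon,
)


@pytest.fixture
def small_genome() -> GenomeModel:
    """A 5 kb chromosome plus a 1 kb plasmid, random but reproducible."""
    chrom = random_replicon("chr", 5000, 0.60, seed=101, role="chromosome")
    plasmid = random_replicon("pA", 1000, 0.55, seed=102, role="plasmid")
    return GenomeModel([chrom, plasmid])


@pytest.fixture
def small_model(small_genome) -> PopulationModel:
    return PopulationModel(genome=small_genome)


@pytest.fixture
def tiny_replicon() -> Replicon:
    """A fixed 40 bp sequence for hand-countable window statistics."""
    return Replicon.from_sequence(
        "tiny", "GGGGGGCCGGGCACGTACGTAAAATTTTACGTNNGCATGC", role="chromosome"
    )
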