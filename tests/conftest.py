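import random

import pytest

from paleocar.genome_model import Genome
from paleocar.local_dcj import ScoringParams


@pytest.fixture
def params():
    return ScoringParams(L=8, p=0.25)


def random_linear_genome(rng: random.Random, n: int,
                         max_chromosomes: int = 2,
                         genome_id: str = "G") -> Genome:
    """Random non-duplicated genome over markers 1..n with random signs
    and chromosome cuts."""
    markers = [rng.choice([1, -1]) * m for m in rng.sample(range(1, n + 1), n)]
    k = rng.randint(1, min(max_chromosomes, n)) if n else 1
    cuts = sorted(rng.sample(range(1, n), k - 1)) if n > 1 and k > 1 else []
    bounds = [0] + cuts + [n]
    chroms = [markers[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]
    return Genome.from_ints(chroms, genome_id)


def shuffled_balanced_pair(rng: random.Random, n: int):
    """Two random balanced non-duplicated genomes over the same markers."""
    g = random_linear_genome(rng, n, genome_id="G")
    h = random_linear_genome(rng, n, genome_id="H")
    return g, h
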