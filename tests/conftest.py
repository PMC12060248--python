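import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cgnkit.io import Gene
from cgnkit.orthology import RankedPair


def make_pairs(targets, target_chroms=None, pidents=None, qchrom="c1",
               tchrom="d1", ids=None):
    """RankedPairs for query ranks 1..n with the given target ranks."""
    pairs = []
    for i, t in enumerate(targets):
        gid = ids[i] if ids else f"q{i + 1}"
        g = Gene(id=gid, chromosome=qchrom, start=(i + 1) * 1000,
                 end=(i + 1) * 1000 + 500, rank=i + 1)
        pairs.append(RankedPair(
            query=g, target_id=f"t{t}",
            target_chrom=target_chroms[i] if target_chroms else tchrom,
            target_rank=t,
            pident=pidents[i] if pidents else 99.0))
    return pairs


@pytest.fixture
def worked_example_pairs():
    """Seven query genes A..G whose top hits sit in target order
    A B D E F C G (target ranks 1 2 6 3 4 5 7 in query order)."""
    return make_pairs([1, 2, 6, 3, 4, 5, 7],
                      ids=list("ABCDEFG"))


@pytest.fixture(scope="session")
def default_genome_pair():
    from cgnkit.simulate import SimConfig, simulate_genome_pair
    return simulate_genome_pair(SimConfig(seed=1))


@pytest.fixture(scope="session")
def classified_default_pair(default_genome_pair):
    from cgnkit.orthology import classify_genes
    records, blocks = classify_genes(default_genome_pair.genes_a,
                                     default_genome_pair.genes_b,
                                     default_genome_pair.hits)
    return records, blocks


@pytest.fixture(scope="session")
def scaffold_sim():
    from cgnkit.simulate import ScaffoldSimConfig, simulate_scaffold_set
    return simulate_scaffold_set(ScaffoldSimConfig(seed=1))
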