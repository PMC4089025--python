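import numpy as np
import pytest

from h2hreg.genome import GeneModel, GenomicInterval, H2HPair, make_pair_id
from h2hreg.simulate import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def small_dataset():
    """One desk-scale synthetic dataset shared across tests."""
    return generate_all(SyntheticConfig.small(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_interval(rng, chroms=("chr1", "chr2"), span=10000, max_len=500):
    chrom = chroms[int(rng.integers(len(chroms)))]
    start = int(rng.integers(0, span))
    length = int(rng.integers(1, max_len))
    return GenomicInterval(chrom, start, start + length)


def make_pair(pair_idx, chrom="chr1", start=1000, l1=2000, gap=400, l2=2000):
    """A hand-built H2H pair: minus gene then plus gene separated by gap bp."""
    gm = GeneModel(f"M{pair_idx}", GenomicInterval(chrom, start, start + l1), "-")
    gp = GeneModel(
        f"P{pair_idx}",
        GenomicInterval(chrom, start + l1 + gap, start + l1 + gap + l2),
        "+",
    )
    return H2HPair(make_pair_id(gm.gene_id, gp.gene_id), gm, gp, gap)
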