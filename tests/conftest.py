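import numpy as np
import pytest

from altiscan.variants import VariantTable


def make_vt(genotypes, populations, pos=None, contig=None, samples=None):
    """Small VariantTable from a (samples x sites) dosage list."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = G.shape
    pos = np.arange(1, n_sites + 1) * 100 if pos is None else np.asarray(pos)
    contig = np.repeat("chr1", n_sites) if contig is None else np.asarray(contig, dtype=object)
    samples = [f"s{i}" for i in range(n_samples)] if samples is None else samples
    return VariantTable(
        contig=contig,
        pos=pos,
        ref=np.repeat("A", n_sites),
        alt=np.repeat("C", n_sites),
        genotypes=G,
        samples=samples,
        populations=np.asarray(populations, dtype=object),
    )


@pytest.fixture
def two_pop_vt():
    """5+5 diploids, 4 hand-crafted sites."""
    G = [
        [0, 2, 1, 0],
        [0, 2, 1, 0],
        [0, 2, 0, 1],
        [0, 2, 2, 0],
        [0, 2, 1, 0],
        [2, 0, 0, 0],
        [2, 0, 1, 0],
        [2, 0, 0, 0],
        [2, 0, 0, 2],
        [2, 0, 2, 0],
    ]
    pops = ["high"] * 5 + ["low"] * 5
    return make_vt(G, pops)
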