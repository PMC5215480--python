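import numpy as np
import pytest

from multilocus import LocusAlignment, build_container, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    """8 individuals x 4 loci with per-locus presence 5, 6, 8, 5."""
    return worked_example_fixture(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20160812)


def make_container(presence, lengths, rng, labels=None, names=None):
    """Random container from an explicit per-locus presence mask."""
    n_ind = len(presence[0])
    labels = labels or [f"ind{k + 1:02d}" for k in range(n_ind)]
    names = names or [f"locus{k + 1}" for k in range(len(presence))]
    bases = np.array(list("ACGT"))
    loci = []
    for name, mask, length in zip(names, presence, lengths):
        rows = {}
        for label, present in zip(labels, mask):
            if present:
                rows[label] = "".join(
                    bases[rng.integers(0, 4, size=length)]
                )
        loci.append(LocusAlignment(name, rows, "nucleotide"))
    return build_container(loci)


@pytest.fixture
def toy_container():
    """Tiny hand-written 2-locus container over 3 individuals."""
    l1 = LocusAlignment(
        "gene_a", {"s1": "ACGTAC", "s2": "ACGTAC", "s3": "ACCTAC"}
    )
    l2 = LocusAlignment("gene_b", {"s1": "TTTT", "s3": "TTAT"})
    return build_container([l1, l2])
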