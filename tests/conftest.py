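import numpy as np
import pytest

from hzscan.io import LocusAlignment, SampleRecord


def make_alignment(columns, locus_id="loc", region="unlinked", offset=None,
                   prefix="h"):
    """Alignment from a list of per-column base strings (one char per hap)."""
    n = len(columns[0])
    assert all(len(c) == n for c in columns)
    seqs = [
        (f"{prefix}{i}", "".join(col[i] for col in columns)) for i in range(n)
    ]
    return LocusAlignment(locus_id, region, offset, seqs)


def single_site_alignment(bases_a, bases_b, locus_id="loc"):
    """One-column alignment for two populations; returns (aln, names_a, names_b)."""
    seqs = [(f"a{i}", b) for i, b in enumerate(bases_a)]
    seqs += [(f"b{i}", b) for i, b in enumerate(bases_b)]
    aln = LocusAlignment(locus_id, "unlinked", None, seqs)
    return aln, [n for n, _ in seqs[: len(bases_a)]], \
        [n for n, _ in seqs[len(bases_a):]]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diploid_samples():
    """Ten diploids over two populations with 0/1 phenotypes."""
    samples = []
    for i in range(5):
        samples.append(SampleRecord(f"A{i}", "popA", "ab", 0.0,
                                    (f"A{i}_a", f"A{i}_b")))
    for i in range(5):
        samples.append(SampleRecord(f"B{i}", "popB", "ab", 1.0,
                                    (f"B{i}_a", f"B{i}_b")))
    return samples
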