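import numpy as np
import pytest

from m5cfeat.embeddings import EmbeddingTable
from m5cfeat.windows import SiteRecord


@pytest.fixture
def toy_table_k2():
    """k=2, dim=2 table over a handful of 2-mers with distinct vectors."""
    bases = "ACGU"
    vectors = {
        a + b: np.array([float(i * 4 + j + 1), float(-(i * 4 + j + 1))])
        for i, a in enumerate(bases)
        for j, b in enumerate(bases)
    }
    return EmbeddingTable(k=2, dim=2, vectors=vectors)


@pytest.fixture
def zero_table_k4():
    """All 4-mers mapped to 30-dim zero vectors."""
    kmers = [""]
    for _ in range(4):
        kmers = [km + b for km in kmers for b in "ACGU"]
    return EmbeddingTable(k=4, dim=30, vectors={km: np.zeros(30) for km in kmers})


@pytest.fixture
def basis_table_k2():
    """One-hot style: each 2-mer maps to a distinct 16-dim basis vector."""
    bases = "ACGU"
    vectors = {}
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            v = np.zeros(16)
            v[i * 4 + j] = 1.0
            vectors[a + b] = v
    return EmbeddingTable(k=2, dim=16, vectors=vectors)


def make_records(windows, labels):
    return [
        SiteRecord(id=f"r{i}", window=w, label=lab)
        for i, (w, lab) in enumerate(zip(windows, labels))
    ]


@pytest.fixture
def fasta_pair(tmp_path):
    """Write positive/negative FASTA files and return their paths."""

    def _write(pos_windows, neg_windows):
        pos = tmp_path / "pos.fasta"
        neg = tmp_path / "neg.fasta"
        pos.write_text("".join(f">p{i}\n{w}\n" for i, w in enumerate(pos_windows)))
        neg.write_text("".join(f">n{i}\n{w}\n" for i, w in enumerate(neg_windows)))
        return pos, neg

    return _write
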