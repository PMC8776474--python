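"""Reading, validating, and writing k-mer embedding tables.

The on-disk dialect is whitespace-separated text, one k-mer per line::

    TOKEN w1 w2 ... wd

An optional first line of exactly two integers ("count dim", the header
some word-vector exporters emit) is auto-detected and skipped.  Tokens in
the DNA alphabet are transliterated T→U on read, so DNA- and RNA-alphabet
files are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import FormatError, KmerLookupError

RNA_ALPHABET = frozenset("ACGU")

AmbiguityPolicy = Literal["error", "zero"]


def _normalize_kmer(token: str) -> str:
    return token.upper().replace("T", "U")


@dataclass
class EmbeddingTable:
    """A map from k-mers over {A,C,G,U} to fixed-length real vectors.

    Parameters
    ----------
    k : int
        k-mer length; every key has exactly this length.
    dim : int
        Embedding dimensionality; every vector has exactly this length.
    vectors : dict[str, numpy.ndarray]
        The k-mer → vector map.  At most ``4**k`` entries.
    """

    k: int
    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.dim < 1:
            raise ValueError(f"dim must be positive, got {self.dim}")
        for kmer, vec in self.vectors.items():
            if len(kmer) != self.k:
                raise ValueError(f"key {kmer!r} has length {len(kmer)}, expected k={self.k}")
            if not set(kmer) <= RNA_ALPHABET:
                raise ValueError(f"key {kmer!r} contains characters outside {{A,C,G,U}}")
            if np.asarray(vec).shape != (self.dim,):
                raise ValueError(f"vector for {kmer!r} does not have length dim={self.dim}")

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, kmer: str) -> bool:
        return _normalize_kmer(kmer) in self.vectors


def lookup(
    table: EmbeddingTable, kmer: str, policy: AmbiguityPolicy = "error"
) -> np.ndarray:
    """Return the embedding vector for ``kmer``.

    The query is uppercased and T→U transliterated before lookup.  A
    missing k-mer either raises (policy ``"error"``, the default) or is
    mapped to the zero vector (policy ``"zero"``), covering datasets whose
    vector files omit rare k-mers.
    """
    if len(kmer) != table.k:
        raise ValueError(f"query {kmer!r} has length {len(kmer)}, table expects k={table.k}")
    key = _normalize_kmer(kmer)
    vec = table.vectors.get(key)
    if vec is None:
        if policy == "zero":
            return np.zeros(table.dim)
        if policy == "error":
            raise KmerLookupError(f"k-mer {key!r} not present in embedding table")
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    return vec


def _looks_like_count_header(fields: list[str]) -> bool:
    if len(fields) != 2:
        return False
    try:
        int(fields[0]), int(fields[1])
    except ValueError:
        return False
    return True


def read_embeddings(path: str | Path, expected_k: int | None = None) -> EmbeddingTable:
    """Parse an embedding table from whitespace-separated text.

    ``k`` is inferred from the first token and ``dim`` from the first data
    line; every subsequent line must agree.  Raises :class:`FormatError`
    naming the offending line on any inconsistency, and a duplicate-key
    :class:`FormatError` if a token (after T→U) appears twice.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    k: int | None = None
    dim: int | None = None

    with open(path) as fh:
        lines = [(i + 1, line.split()) for i, line in enumerate(fh) if line.strip()]

    if lines and _looks_like_count_header(lines[0][1]):
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: no embedding rows found")

    for lineno, fields in lines:
        token, values = fields[0], fields[1:]
        kmer = _normalize_kmer(token)
        if not set(kmer) <= RNA_ALPHABET:
            raise FormatError(
                f"{path}:{lineno}: token {token!r} contains characters outside the RNA/DNA alphabet"
            )
        if k is None:
            k = len(kmer)
            if expected_k is not None and k != expected_k:
                raise FormatError(
                    f"{path}:{lineno}: token length {k} does not match expected k={expected_k}"
                )
        elif len(kmer) != k:
            raise FormatError(
                f"{path}:{lineno}: token {token!r} has length {len(kmer)}, expected {k}"
            )
        if dim is None:
            dim = len(values)
            if dim == 0:
                raise FormatError(f"{path}:{lineno}: token {token!r} has no vector values")
        elif len(values) != dim:
            raise FormatError(
                f"{path}:{lineno}: row has {len(values)} values, expected {dim}"
            )
        if kmer in vectors:
            raise FormatError(f"{path}:{lineno}: duplicate token {kmer!r}")
        try:
            vectors[kmer] = np.array([float(v) for v in values])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc

    assert k is not None and dim is not None
    return EmbeddingTable(k=k, dim=dim, vectors=vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table in the same dialect ``read_embeddings`` consumes.

    Values use full ``repr`` precision so a write/read round trip is exact.
    No header line is emitted.
    """
    with open(path, "w") as fh:
        for kmer in sorted(table.vectors):
            values = " ".join(repr(float(v)) for v in table.vectors[kmer])
            fh.write(f"{kmer} {values}\n")
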