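"""Window encoding: k-mer slots × embedding dimensions.

Every 4-mer start position in a 41-nt window whose span does not touch
the centre (the candidate site, identical in all windows) is a *slot*;
with the defaults that leaves 34 slots (starts 1–17 and 22–38).  Each
slot contributes the full embedding vector of its 4-mer, so the default
feature space is 34 × 30 = 1020 columns.  Features are ordered
slot-major — all ``dim`` components of slot 1, then slot 2, … — and the
slot→start mapping is kept as per-feature provenance so selected
features can later be mapped back to window positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import AmbiguityPolicy, EmbeddingTable, lookup
from .errors import KmerLookupError
from .windows import POSITIVE, SiteRecord

DEFAULT_WINDOW_LEN = 41
DEFAULT_CENTER = 21


def valid_kmer_starts(
    window_len: int = DEFAULT_WINDOW_LEN, k: int = 4, center: int = DEFAULT_CENTER
) -> list[int]:
    """All 1-based k-mer start positions whose span avoids the centre.

    A start ``s`` covers positions ``s … s+k-1``; starts covering
    ``center`` are discarded because that position is constant across
    windows.  Defaults give the 34 starts [1–17] ∪ [22–38].
    """
    if not 1 <= center <= window_len:
        raise ValueError(f"center {center} outside window of length {window_len}")
    if k < 1 or k > window_len:
        raise ValueError(f"k={k} invalid for window of length {window_len}")
    return [
        s for s in range(1, window_len - k + 2) if not (s <= center <= s + k - 1)
    ]


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one feature column.

    ``index`` is the 1-based feature index; ``slot`` the 1-based slot it
    belongs to (``ceil(index / dim)``); ``start`` the slot's 1-based k-mer
    start within the window; ``emb_dim`` the 1-based embedding component
    (``(index-1) mod dim + 1``); ``covered_positions`` the k window
    positions ``{start, …, start+k-1}``.
    """

    index: int
    slot: int
    start: int
    emb_dim: int
    covered_positions: frozenset[int]

    @property
    def name(self) -> str:
        return f"s{self.slot}d{self.emb_dim}"


def descriptor_for(
    index: int, dim: int, starts: list[int], k: int
) -> FeatureDescriptor:
    """Build the descriptor for a 1-based feature index (slot-major order)."""
    n_features = dim * len(starts)
    if not 1 <= index <= n_features:
        raise ValueError(f"feature index {index} outside [1, {n_features}]")
    slot = (index - 1) // dim + 1
    emb_dim = (index - 1) % dim + 1
    start = starts[slot - 1]
    return FeatureDescriptor(
        index=index,
        slot=slot,
        start=start,
        emb_dim=emb_dim,
        covered_positions=frozenset(range(start, start + k)),
    )


def make_descriptors(dim: int, starts: list[int], k: int) -> list[FeatureDescriptor]:
    return [descriptor_for(i, dim, starts, k) for i in range(1, dim * len(starts) + 1)]


@dataclass
class FeatureMatrix:
    """Encoded samples with per-feature provenance.

    ``values`` is the n_samples × n_features matrix, ``descriptors`` one
    :class:`FeatureDescriptor` per column (indices 1…n_features in
    order), ``labels`` the per-sample class strings, ``ids`` the record
    identifiers.
    """

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.descriptors) != m:
            raise ValueError(f"{len(self.descriptors)} descriptors for {m} columns")
        if [d.index for d in self.descriptors] != list(range(1, m + 1)):
            raise ValueError("descriptor indices must be 1…n_features in order")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if not self.ids:
            self.ids = [f"sample_{i + 1}" for i in range(n)]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Labels as ±1 (+1 positive, −1 negative)."""
        return np.where(np.asarray(self.labels) == POSITIVE, 1, -1)


def encode_windows(
    records: list[SiteRecord],
    table: EmbeddingTable,
    center: int = DEFAULT_CENTER,
    policy: AmbiguityPolicy = "error",
) -> FeatureMatrix:
    """Encode windows into the slot-major embedding feature matrix.

    Row *i*, slot *j*, component *d* holds component *d* of the embedding
    of the k-mer starting at the *j*-th valid start of window *i*.
    """
    if not records:
        raise ValueError("no records to encode")
    window_len = len(records[0].window)
    if any(len(r.window) != window_len for r in records):
        raise ValueError("all windows must have the same length")
    k = table.k
    starts = valid_kmer_starts(window_len, k, center)
    descriptors = make_descriptors(table.dim, starts, k)

    values = np.empty((len(records), len(starts) * table.dim))
    for i, rec in enumerate(records):
        for j, s in enumerate(starts):
            kmer = rec.window[s - 1 : s - 1 + k]
            try:
                vec = lookup(table, kmer, policy=policy)
            except KmerLookupError as exc:
                raise KmerLookupError(
                    f"sample {rec.id!r}, slot {j + 1} (start {s}): {exc}"
                ) from exc
            values[i, j * table.dim : (j + 1) * table.dim] = vec
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        labels=[r.label for r in records],
        ids=[r.id for r in records],
    )


def write_matrix(matrix: FeatureMatrix, path: str | Path, header: str | None = None) -> None:
    """Export as TSV: id, label, then one column per feature ("s{slot}d{dim}")."""
    df = pd.DataFrame(matrix.values, columns=[d.name for d in matrix.descriptors])
    df.insert(0, "label", matrix.labels)
    df.insert(0, "id", matrix.ids)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_descriptors(matrix: FeatureMatrix, path: str | Path, header: str | None = None) -> None:
    """Sidecar TSV of feature provenance: index, slot, start, emb_dim, positions."""
    rows = [
        {
            "index": d.index,
            "slot": d.slot,
            "start": d.start,
            "emb_dim": d.emb_dim,
            "positions": ",".join(map(str, sorted(d.covered_positions))),
        }
        for d in matrix.descriptors
    ]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_matrix(path: str | Path, k: int, starts: list[int], dim: int) -> FeatureMatrix:
    """Re-import a matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    descriptors = make_descriptors(dim, starts, k)
    expected = ["id", "label"] + [d.name for d in descriptors]
    if list(df.columns) != expected:
        raise ValueError("matrix columns do not match the expected slot/dim layout")
    return FeatureMatrix(
        values=df.iloc[:, 2:].to_numpy(float),
        descriptors=descriptors,
        labels=df["label"].tolist(),
        ids=df["id"].astype(str).tolist(),
    )
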