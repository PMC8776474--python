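"""Synthetic benchmark data: planted-motif windows and seeded embeddings.

Real candidate-site datasets cannot be bundled, so this module generates
their structural stand-ins: balanced labeled 41-nt windows whose only
class signal is a set of planted positional motifs (e.g., a downstream
UCCA at positions 22–25 or a G-rich run, the two sequence contexts
characteristic of the two known site classes), on an i.i.d. background;
and deterministic k-mer embedding tables.  Negatives are drawn from the
same background as positives minus the motif signal, so any recoverable
class difference is attributable to the planted motifs.

Seeding uses a single master seed expanded into one child stream per
record, so a record's content is stable under partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import EmbeddingTable
from .errors import ValidationError
from .windows import NEGATIVE, POSITIVE, SiteRecord

BASES = "ACGU"

UNIFORM_COMPOSITION = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}


@dataclass(frozen=True)
class MotifSpec:
    """One plantable positional motif.

    ``pattern`` is an RNA string placed at 1-based window position
    ``start``; it is planted with probability ``presence_prob`` in
    positive samples and ``background_prob`` in negative ones.
    """

    pattern: str
    start: int
    presence_prob: float = 1.0
    background_prob: float = 0.0

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set(BASES):
            raise ValueError(f"pattern {self.pattern!r} must be nonempty over {{A,C,G,U}}")
        if self.start < 1:
            raise ValueError("start must be >= 1")
        for p in (self.presence_prob, self.background_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def span(self) -> range:
        return range(self.start, self.start + len(self.pattern))


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the benchmark dataset sizes
    (120 positives + 120 negatives of 41-nt windows, site at 21)."""

    n_pos: int = 120
    n_neg: int = 120
    window_len: int = 41
    center: int = 21
    motifs: list[MotifSpec] = field(default_factory=list)
    base_composition: dict[str, float] = field(
        default_factory=lambda: dict(UNIFORM_COMPOSITION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be nonnegative")
        if not 1 <= self.center <= self.window_len:
            raise ValueError("center must lie inside the window")
        probs = [self.base_composition.get(b, 0.0) for b in BASES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("base_composition must be a distribution over A,C,G,U")
        for m in self.motifs:
            if m.start + len(m.pattern) - 1 > self.window_len:
                raise ValidationError(
                    f"motif {m.pattern!r}@{m.start} extends past the window"
                )
        spans: set[int] = set()
        for m in self.motifs:
            overlap = spans & set(m.span)
            if overlap:
                raise ValidationError(
                    f"motif {m.pattern!r}@{m.start} overlaps another motif at "
                    f"positions {sorted(overlap)}"
                )
            spans.update(m.span)


def _one_window(rng: np.random.Generator, config: SynthConfig, positive: bool) -> str:
    probs = np.array([config.base_composition[b] for b in BASES])
    chars = list(rng.choice(list(BASES), size=config.window_len, p=probs))
    for motif in config.motifs:
        prob = motif.presence_prob if positive else motif.background_prob
        if rng.random() < prob:
            for offset, ch in enumerate(motif.pattern):
                chars[motif.start - 1 + offset] = ch
    chars[config.center - 1] = "C"  # candidate site: always a cytosine
    return "".join(chars)


def generate_dataset(config: SynthConfig) -> list[SiteRecord]:
    """Generate the labeled window set described by ``config``.

    Reproducible: the same config (including seed) yields identical
    records; each record has its own child random stream.
    """
    n_total = config.n_pos + config.n_neg
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    records: list[SiteRecord] = []
    for i in range(n_total):
        positive = i < config.n_pos
        rng = np.random.default_rng(streams[i])
        window = _one_window(rng, config, positive)
        label = POSITIVE if positive else NEGATIVE
        idx = i + 1 if positive else i - config.n_pos + 1
        records.append(SiteRecord(id=f"{'pos' if positive else 'neg'}_{idx}", window=window, label=label))
    return records


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in BASES]
    return kmers


def _quasi_orthogonal_frame(
    rng: np.random.Generator,
    n_vectors: int,
    dim: int,
    max_abs_cosine: float,
    max_iter: int = 5000,
) -> np.ndarray:
    """Unit vectors with pairwise |cos| strictly below ``max_abs_cosine``.

    Starts from random Gaussian directions and iteratively pushes each
    violating pair apart (a repulsion/alternating-projection scheme for
    line packings); deterministic for a given generator state.  Raises
    when the requested coherence is infeasibly tight for (n, dim).
    """
    V = rng.standard_normal((n_vectors, dim))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    # push slightly past the bound so the final inequality is strict
    target = max_abs_cosine * 0.98
    for _ in range(max_iter):
        G = V @ V.T
        np.fill_diagonal(G, 0.0)
        worst = np.abs(G).max()
        if worst < max_abs_cosine:
            return V
        excess = np.where(np.abs(G) > target, G - np.sign(G) * target, 0.0)
        V -= 0.5 * excess @ V
        V /= np.linalg.norm(V, axis=1, keepdims=True)
    raise RuntimeError(
        f"could not pack {n_vectors} directions with |cos| < {max_abs_cosine} "
        f"in {dim} dimensions"
    )


def generate_embeddings(
    k: int = 4,
    dim: int = 30,
    scheme: str = "gaussian",
    seed: int = 0,
    max_abs_cosine: float = 0.5,
) -> EmbeddingTable:
    """A seeded-deterministic embedding table covering all 4**k k-mers.

    ``gaussian``: i.i.d. standard-normal components.  ``near_orthogonal``:
    unit vectors drawn by rejection so that every pair has absolute
    cosine similarity below ``max_abs_cosine`` — distinct k-mers stay
    separable even when the number of k-mers exceeds the dimension.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    kmers = _all_kmers(k)
    if scheme == "gaussian":
        vectors = {km: rng.standard_normal(dim) for km in kmers}
    elif scheme == "near_orthogonal":
        V = _quasi_orthogonal_frame(rng, len(kmers), dim, max_abs_cosine)
        vectors = {km: V[i] for i, km in enumerate(kmers)}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return EmbeddingTable(k=k, dim=dim, vectors=vectors)
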