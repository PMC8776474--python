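"""Labeled candidate-site windows.

A candidate m⁵C site is analysed through the fixed-length window of
sequence centred on it: with the default flank of 20 nt the window is
41 nt long and the candidate cytosine sits at position 21 (1-based).
Windows arrive either pre-cut (one FASTA record per window) or are cut
here from full sequences with :func:`extract_window`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import AlphabetError, BoundaryError, FormatError, ValidationError

_VALID = frozenset("ACGU")

POSITIVE = "positive"
NEGATIVE = "negative"


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class SiteRecord:
    """One labeled candidate-site window.

    ``window`` is the RNA string of length ``2*flank + 1`` with the
    candidate site at its centre; ``label`` is ``"positive"`` or
    ``"negative"``; ``source_position`` optionally records the 1-based
    coordinate of the centre site in the sequence it was cut from.
    """

    id: str
    window: str
    label: str
    source_position: int | None = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 'positive' or 'negative', got {self.label!r}")

    @property
    def center(self) -> str:
        """The centre character (the candidate site itself)."""
        return self.window[len(self.window) // 2]


def extract_window(sequence: str, position: int, flank: int = 20) -> str:
    """Cut the ``2*flank + 1``-long window centred on a 1-based position.

    The window comprises ``flank`` nt upstream, the site, and ``flank`` nt
    downstream.  Raises :class:`BoundaryError` reporting the deficit when
    the sequence does not extend ``flank`` nt on both sides.
    """
    if flank < 0:
        raise ValueError(f"flank must be nonnegative, got {flank}")
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    missing_up = flank - (position - 1)
    missing_down = (position + flank) - len(sequence)
    if missing_up > 0 or missing_down > 0:
        parts = []
        if missing_up > 0:
            parts.append(f"{missing_up} nt upstream")
        if missing_down > 0:
            parts.append(f"{missing_down} nt downstream")
        raise BoundaryError(
            f"position {position}: insufficient flanking sequence ({', '.join(parts)} missing)"
        )
    return sequence[position - 1 - flank : position + flank]


def _validate_window(rec_id: str, window: str, flank: int, center_check: bool) -> str:
    window = _normalize(window)
    expected = 2 * flank + 1
    if len(window) != expected:
        raise FormatError(
            f"record {rec_id!r}: window length {len(window)}, expected {expected}"
        )
    bad = set(window) - _VALID
    if bad:
        raise AlphabetError(
            f"record {rec_id!r}: characters {sorted(bad)} outside {{A,C,G,U,T}}"
        )
    if center_check and window[flank] != "C":
        raise ValidationError(
            f"record {rec_id!r}: centre position {flank + 1} is {window[flank]!r}, expected 'C'"
        )
    return window


def read_site_fasta(
    positive_path: str | Path,
    negative_path: str | Path,
    flank: int = 20,
    center_check: bool = True,
) -> list[SiteRecord]:
    """Read the positive/negative FASTA pair into labeled records.

    Sequences are uppercased and T→U transliterated before validation.
    ``center_check`` (default on) requires the centre character to be C
    for both labels — negatives are cytosine sites too.
    """
    records: list[SiteRecord] = []
    for path, label in ((positive_path, POSITIVE), (negative_path, NEGATIVE)):
        for rec in SeqIO.parse(str(path), "fasta"):
            window = _validate_window(rec.id, str(rec.seq), flank, center_check)
            records.append(SiteRecord(id=rec.id, window=window, label=label))
    return records


def read_labeled_fasta(
    path: str | Path, flank: int = 20, center_check: bool = True
) -> list[SiteRecord]:
    """Single-file alternative: labels parsed from ``label=1|0`` in headers."""
    records: list[SiteRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if "label=1" in desc:
            label = POSITIVE
        elif "label=0" in desc:
            label = NEGATIVE
        else:
            raise FormatError(f"record {rec.id!r}: header lacks a 'label=1|0' field")
        window = _validate_window(rec.id, str(rec.seq), flank, center_check)
        records.append(SiteRecord(id=rec.id, window=window, label=label))
    return records


def write_site_fasta(
    records: list[SiteRecord], positive_path: str | Path, negative_path: str | Path
) -> None:
    """Write records back out as the positive/negative FASTA pair."""
    with open(positive_path, "w") as pos, open(negative_path, "w") as neg:
        for rec in records:
            fh = pos if rec.label == POSITIVE else neg
            fh.write(f">{rec.id}\n{rec.window}\n")
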