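"""Feature-frequency analysis: map selected features back to positions.

Each encoded feature originates from one k-mer slot and therefore covers
k consecutive window positions.  Counting, over the optimum feature
subset of a model, how many selected features cover each position yields
a per-position frequency profile — the quantity that localizes the
discriminative sequence signal around the candidate site.  Each feature
contributes 1 to each of its k positions (features are counted, not
weighted by their ranking scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .encode import FeatureDescriptor
from .errors import ValidationError


@dataclass
class PositionFrequency:
    """Per-window-position counts of selected features.

    ``counts`` maps every position 1…window_len to the number of selected
    features covering it; ``n_features`` is the number of features
    counted, so the counts sum to k·n_features.
    """

    counts: dict[int, int]
    n_features: int

    @property
    def window_len(self) -> int:
        return len(self.counts)

    def max_positions(self) -> list[int]:
        """Positions attaining the maximum count (empty-selection → all)."""
        peak = max(self.counts.values())
        return [p for p, c in self.counts.items() if c == peak]


def position_frequencies(
    selected: list[FeatureDescriptor], window_len: int
) -> PositionFrequency:
    """Count, per window position, the selected features covering it."""
    counts = {p: 0 for p in range(1, window_len + 1)}
    for desc in selected:
        for p in desc.covered_positions:
            if not 1 <= p <= window_len:
                raise ValidationError(
                    f"feature {desc.index}: covered position {p} outside window 1..{window_len}"
                )
            counts[p] += 1
    return PositionFrequency(counts=counts, n_features=len(selected))


def write_frequency_outputs(
    freq: PositionFrequency,
    path_prefix: str | Path,
    title: str | None = None,
    header: str | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (position, count) and ``<prefix>.png`` bar chart."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".tsv")
    png_path = prefix.with_suffix(".png")

    positions = sorted(freq.counts)
    df = pd.DataFrame({"position": positions, "count": [freq.counts[p] for p in positions]})
    with open(tsv_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(df["position"], df["count"], color="steelblue")
    ax.set_xlabel("window position (nt)")
    ax.set_ylabel("number of selected features")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return tsv_path, png_path
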