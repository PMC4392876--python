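"""Summit-centred tag-density matrices and mean profiles.

Tags are single-bp positions (5' ends); no fragment extension is applied.
Peaks are treated as unstranded, so bins always run left-to-right in genome
coordinates.  With the defaults (5 kb flank either side of the summit,
50 bp bins) each peak contributes a 200-bin row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PeakSet

TagPositions = dict[str, np.ndarray]  # chrom -> sorted int positions (with repeats)


@dataclass
class DensityMatrix:
    values: np.ndarray  # peaks x bins, tag counts
    peak_ids: list[str]
    flank: int
    bin_size: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    def to_frame(self) -> pd.DataFrame:
        offsets = np.arange(self.n_bins) * self.bin_size - self.flank
        return pd.DataFrame(
            self.values, index=self.peak_ids, columns=[f"bin_{o}" for o in offsets]
        )


def read_tags(path: str) -> TagPositions:
    """Read single-bp tag positions from 4-column BED (chrom, pos, pos+1, count)."""
    tags: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, pos = f[0], int(f[1])
            count = int(f[3]) if len(f) > 3 and f[3] not in (".", "") else 1
            tags.setdefault(chrom, []).extend([pos] * count)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in tags.items()}


def write_tags(tags: TagPositions, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tags):
            positions, counts = np.unique(tags[chrom], return_counts=True)
            for pos, count in zip(positions, counts):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{count}\n")


def density_matrix(
    tags: TagPositions, peaks: PeakSet, flank: int = 5000, bin_size: int = 50
) -> DensityMatrix:
    """Count tags in ``bin_size``-bp bins across ±``flank`` of each summit.

    Bin j of a peak covers [summit - flank + j*bin_size,
    summit - flank + (j+1)*bin_size).
    """
    if flank % bin_size != 0:
        raise ValueError(f"flank {flank} not divisible by bin_size {bin_size}")
    n_bins = 2 * flank // bin_size
    ordered = peaks.sorted()
    values = np.zeros((len(ordered), n_bins), dtype=np.int64)
    for i, p in enumerate(ordered):
        positions = tags.get(p.chrom)
        if positions is None or len(positions) == 0:
            continue
        lo = np.searchsorted(positions, p.summit - flank, side="left")
        hi = np.searchsorted(positions, p.summit + flank, side="left")
        local = positions[lo:hi]
        if len(local):
            bins = (local - (p.summit - flank)) // bin_size
            values[i] = np.bincount(bins, minlength=n_bins)
    return DensityMatrix(values, [p.peak_id for p in ordered], flank, bin_size)


def mean_profile(m: DensityMatrix) -> np.ndarray:
    """Per-bin mean tag count across peaks (the aggregate profile curve)."""
    if m.values.shape[0] == 0:
        raise ValueError("empty density matrix")
    return m.values.mean(axis=0)


def order_rows_by_signal(m: DensityMatrix) -> list[str]:
    """Heatmap display order: descending total row signal, ties by peak id."""
    totals = m.values.sum(axis=1)
    order = sorted(range(len(m.peak_ids)), key=lambda i: (-totals[i], m.peak_ids[i]))
    return [m.peak_ids[i] for i in order]
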