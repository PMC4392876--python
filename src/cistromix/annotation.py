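"""Peak-to-gene assignment by TSS windows and genomic feature distribution.

A peak is ascribed to a gene when its summit falls within a strand-oriented
window around the TSS (default 5 kb upstream to 1 kb downstream), or when
the peak interval comes within ``promoter_pad`` (default 1 kb) of a gene's
core promoter.  The core promoter is the 5'UTR plus the 1 kb upstream of
the TSS.  Among candidate genes the one with the smallest |summit - TSS|
wins; ties break to the lexicographically smallest gene id.

Feature classification assigns each peak SUMMIT to one of five classes with
precedence core_promoter > exon > intron > downstream_1kb >
distal_intergenic, and compares the observed class fractions with the
fraction of genome base pairs each class occupies under the same
precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, Peak, PeakSet

FEATURE_CLASSES = [
    "core_promoter",
    "exon",
    "intron",
    "downstream_1kb",
    "distal_intergenic",
]

# paint codes, ascending precedence (higher code wins when painting)
_CLASS_CODE = {
    "distal_intergenic": 0,
    "downstream_1kb": 1,
    "intron": 2,
    "exon": 3,
    "core_promoter": 4,
}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}


@dataclass
class PeakAnnotation:
    peak_id: str
    gene_id: Optional[str]
    relation: str  # upstream_window | downstream_window | promoter_proximal | unassigned
    distance_to_tss: Optional[int]
    alternates: list[str] = field(default_factory=list)


@dataclass
class FeatureDistribution:
    classes: list[str]
    observed_fraction: np.ndarray
    background_fraction: np.ndarray


def _signed_distance(gene: GeneModel, summit: int) -> int:
    """Signed summit-to-TSS distance; negative = upstream in gene orientation."""
    if gene.strand == "+":
        return summit - gene.tss
    return gene.tss - summit


def core_promoter_pieces(gene: GeneModel, upstream_pad: int = 1000) -> list[GenomicInterval]:
    """The core promoter: 1 kb upstream of the TSS plus the 5'UTR if present."""
    pieces = []
    if gene.strand == "+":
        if gene.tss - upstream_pad < gene.tss:
            pieces.append(GenomicInterval(gene.chrom, gene.tss - upstream_pad, gene.tss))
    else:
        pieces.append(GenomicInterval(gene.chrom, gene.tss, gene.tss + upstream_pad))
    if gene.utr5 is not None:
        pieces.append(gene.utr5)
    return pieces


def _gene_matches(
    gene: GeneModel,
    peak: Peak,
    upstream: int,
    downstream: int,
    promoter_pad: int,
) -> Optional[str]:
    """Which clause (if any) admits this gene as a candidate for the peak."""
    if gene.chrom != peak.chrom:
        return None
    d = _signed_distance(gene, peak.summit)
    if -upstream <= d <= downstream:
        return "upstream_window" if d < 0 else "downstream_window"
    for piece in core_promoter_pieces(gene):
        padded_start = piece.start - promoter_pad
        padded_end = piece.end + promoter_pad
        if max(peak.start, padded_start) < min(peak.end, padded_end):
            return "promoter_proximal"
    return None


def assign_nearest_gene(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    upstream: int = 5000,
    downstream: int = 1000,
    promoter_pad: int = 1000,
) -> list[PeakAnnotation]:
    """Assign each peak to its nearest eligible gene.

    Every peak receives exactly one annotation record; peaks with no
    candidate gene are returned as unassigned.
    """
    if not genes:
        raise ValueError("gene collection is empty")
    if upstream < 0 or downstream < 0 or promoter_pad < 0:
        raise ValueError("windows must be non-negative")

    # candidate lookup via interval tree over the widest reach of either clause
    tree_by_chrom: dict[str, IntervalTree] = {}
    for gi, gene in enumerate(genes):
        reach = max(upstream, downstream, promoter_pad + 1000)
        lo = gene.start - reach - promoter_pad
        hi = gene.end + reach + promoter_pad
        tree_by_chrom.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gi)

    annotations = []
    for peak in peaks:
        tree = tree_by_chrom.get(peak.chrom)
        candidates: list[tuple[int, str, GeneModel]] = []
        if tree is not None:
            for iv in tree.overlap(peak.start, peak.end):
                gene = genes[iv.data]
                clause = _gene_matches(gene, peak, upstream, downstream, promoter_pad)
                if clause is not None:
                    candidates.append(
                        (abs(_signed_distance(gene, peak.summit)), clause, gene)
                    )
        if not candidates:
            annotations.append(PeakAnnotation(peak.peak_id, None, "unassigned", None))
            continue
        candidates.sort(key=lambda c: (c[0], c[2].gene_id))
        _, clause, winner = candidates[0]
        annotations.append(
            PeakAnnotation(
                peak.peak_id,
                winner.gene_id,
                clause,
                _signed_distance(winner, peak.summit),
                alternates=[c[2].gene_id for c in candidates[1:]],
            )
        )
    return annotations


def _paint(arr: np.ndarray, start: int, end: int, code: int) -> None:
    lo, hi = max(0, start), min(len(arr), end)
    if lo < hi:
        view = arr[lo:hi]
        np.maximum(view, code, out=view)


def _genome_class_maps(
    genes: Sequence[GeneModel], genome_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    maps = {c: np.zeros(n, dtype=np.uint8) for c, n in genome_lengths.items()}
    for gene in genes:
        arr = maps.get(gene.chrom)
        if arr is None:
            continue
        if gene.strand == "+":
            down = (gene.tes, gene.tes + 1000)
        else:
            down = (gene.tes - 1000, gene.tes)
        _paint(arr, *down, _CLASS_CODE["downstream_1kb"])
        _paint(arr, gene.start, gene.end, _CLASS_CODE["intron"])
        for exon in gene.exons:
            _paint(arr, exon.start, exon.end, _CLASS_CODE["exon"])
        for piece in core_promoter_pieces(gene):
            _paint(arr, piece.start, piece.end, _CLASS_CODE["core_promoter"])
    return maps


def classify_summit(
    peak: Peak, genes: Sequence[GeneModel], genome_lengths: dict[str, int]
) -> str:
    """Feature class of a single peak summit (mainly for interactive use)."""
    maps = _genome_class_maps(genes, genome_lengths)
    return _CODE_CLASS[int(maps[peak.chrom][peak.summit])]


def feature_distribution(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    genome_lengths: dict[str, int],
) -> FeatureDistribution:
    """Observed summit class fractions vs genome-wide background fractions.

    Both vectors are over ``FEATURE_CLASSES`` and each sums to 1.
    """
    for p in peaks:
        if p.chrom not in genome_lengths:
            raise ValueError(
                f"peak {p.peak_id}: chromosome {p.chrom!r} absent from genome lengths"
            )
    maps = _genome_class_maps(genes, genome_lengths)

    observed = np.zeros(len(FEATURE_CLASSES))
    for p in peaks:
        code = int(maps[p.chrom][p.summit])
        observed[FEATURE_CLASSES.index(_CODE_CLASS[code])] += 1
    if len(peaks):
        observed /= len(peaks)

    background = np.zeros(len(FEATURE_CLASSES))
    total = float(sum(genome_lengths.values()))
    for arr in maps.values():
        counts = np.bincount(arr, minlength=5)
        for code, count in enumerate(counts):
            background[FEATURE_CLASSES.index(_CODE_CLASS[code])] += count
    background /= total
    return FeatureDistribution(list(FEATURE_CLASSES), observed, background)
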