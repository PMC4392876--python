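"""Interval and peak data model, overlap semantics, and BED/GTF I/O.

Coordinates are 0-based, half-open throughout.  BED input is taken as-is;
GTF input is converted at the parsing boundary (start - 1).  Peak FDR is
stored on the MACS percent scale (0-100), so a threshold of "FDR < 10"
means < 10%.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval must have start < end, got [{self.start}, {self.end}) "
                f"on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called binding region with summit, FDR (%) and tag density."""

    interval: GenomicInterval
    summit: int
    fdr: float
    tag_density: float
    peak_id: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.fdr < 0:
            raise ValueError(f"peak {self.peak_id}: fdr must be >= 0, got {self.fdr}")
        if self.tag_density < 0:
            raise ValueError(
                f"peak {self.peak_id}: tag_density must be >= 0, got {self.tag_density}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class PeakSet:
    """An ordered collection of peaks with unique ids."""

    peaks: list[Peak] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate peak_id in set {self.label!r}: {dup!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end, p.peak_id)),
            label=self.label,
        )


@dataclass
class GeneModel:
    """A stranded gene with TSS, exons and optional 5'UTR.

    ``tss``/``tes`` are strand-oriented: the TSS of a minus-strand gene is
    the higher coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes ({self.tss})")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


def overlap_fraction(a: Peak, b: Peak) -> float:
    """Fraction of the SHORTER of two peaks covered by their intersection.

    Symmetric in its arguments; cross-chromosome pairs score 0.  This is the
    replicate-overlap measure used for consensus calling: 0.5 means half of
    the smaller peak lies inside the larger one.
    """
    inter = a.interval.intersection_length(b.interval)
    if inter == 0:
        return 0.0
    return inter / min(a.length, b.length)


# ---------------------------------------------------------------------------
# Peak I/O: delimited text with a header row. Provenance lines start with '#'.
# Canonical BED6+ column names; 'summit' dialect is either "absolute" or
# "offset" (offset from peak start, the MACS summit convention).
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "tag_density",
    "strand",
    "summit_offset",
    "fdr_percent",
]

_SUMMIT_ALIASES = {"summit", "summit_offset", "abs_summit"}
_FDR_ALIASES = {"fdr", "fdr_percent", "fdr(%)"}
_TD_ALIASES = {"tag_density", "td", "tags", "score"}
_NAME_ALIASES = {"name", "peak_id", "id"}


def read_peaks(path: str, dialect: str = "offset", label: str = "") -> PeakSet:
    """Read a peak table into a :class:`PeakSet`.

    Parameters
    ----------
    path
        Tab- or comma-delimited text with a header naming at least
        chrom/start/end, a summit column, an FDR column and a tag-density
        column.  Lines starting with '#' are skipped.
    dialect
        "offset" if the summit column stores offset-from-start (MACS style),
        "absolute" if it stores an absolute coordinate.
    """
    if dialect not in ("offset", "absolute"):
        raise ValueError(f"unknown summit dialect {dialect!r}")
    peaks: list[Peak] = []
    label = label or os.path.splitext(os.path.basename(path))[0]
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(sep)]
            if header is None:
                header = [f.lower() for f in fields]
                continue
            try:
                row = dict(zip(header, fields))
                chrom = row["chrom"]
                start = int(row["start"])
                end = int(row["end"])
                summit_raw = float(_lookup(row, _SUMMIT_ALIASES, lineno))
                fdr = float(_lookup(row, _FDR_ALIASES, lineno))
                td = float(_lookup(row, _TD_ALIASES, lineno))
                name = _lookup(row, _NAME_ALIASES, lineno, default=f"peak_{lineno}")
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            summit = int(summit_raw) + (start if dialect == "offset" else 0)
            try:
                interval = GenomicInterval(chrom, start, end)
                peaks.append(
                    Peak(interval, summit, fdr, td, peak_id=name, source=label)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(peaks, label=label)


def _lookup(row: dict, aliases: set[str], lineno: int, default=None):
    for key in aliases:
        if key in row:
            return row[key]
    if default is not None:
        return default
    raise KeyError(f"line {lineno}: none of {sorted(aliases)} present")


def write_peaks(peaks: PeakSet, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write peaks in the canonical BED6+ dialect (summit as offset)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_PEAK_COLUMNS) + "\n")
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t"
                f"{p.tag_density:g}\t.\t{p.summit - p.start}\t{p.fdr:g}\n"
            )


# ---------------------------------------------------------------------------
# Gene model I/O: BED12 (parsed directly) or GTF (via gffutils).
# ---------------------------------------------------------------------------


def read_genes(path: str, fmt: Optional[str] = None) -> list[GeneModel]:
    """Read gene models from BED12 or GTF.

    The TSS is derived from strand: interval start for '+', interval end
    for '-'.  For BED12, the 5'UTR is taken as the region between the TSS
    and the CDS edge (thickStart/thickEnd).  Returns genes sorted by id.
    """
    if fmt is None:
        fmt = "gtf" if path.endswith((".gtf", ".gff", ".gff3")) else "bed12"
    if fmt == "bed12":
        genes = _read_genes_bed12(path)
    elif fmt == "gtf":
        genes = _read_genes_gtf(path)
    else:
        raise ValueError(f"unknown gene format {fmt!r}")
    if not genes:
        log.warning("no gene models parsed from %s", path)
    return sorted(genes, key=lambda g: g.gene_id)


def _read_genes_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + o, start + o + s)
                for o, s in zip(offsets, sizes)
            ]
            if strand == "+":
                tss, tes = start, end
                utr5 = (
                    GenomicInterval(chrom, start, thick_start)
                    if thick_start > start
                    else None
                )
            elif strand == "-":
                tss, tes = end, start
                utr5 = (
                    GenomicInterval(chrom, thick_end, end) if thick_end < end else None
                )
            else:
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            genes.append(GeneModel(name, chrom, strand, tss, tes, exons, utr5))
    return genes


def _read_genes_gtf(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    feature_types = set(db.featuretypes())
    parent_type = "gene" if "gene" in feature_types else "transcript"
    for g in db.features_of_type(parent_type):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id}: unknown strand symbol {g.strand!r}")
        start0 = g.start - 1  # GTF is 1-based inclusive
        if g.strand == "+":
            tss, tes = start0, g.end
        else:
            tss, tes = g.end, start0
        exons = [
            GenomicInterval(g.seqid, e.start - 1, e.end)
            for e in db.children(g, featuretype="exon")
        ]
        utr5 = None
        utrs = [
            GenomicInterval(g.seqid, u.start - 1, u.end)
            for u in db.children(g, featuretype=("five_prime_utr", "5UTR"))
        ]
        if utrs:
            utr5 = GenomicInterval(
                g.seqid, min(u.start for u in utrs), max(u.end for u in utrs)
            )
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        genes.append(GeneModel(gene_id, g.seqid, g.strand, tss, tes, exons, utr5))
    return genes


def read_genome_lengths(path: str) -> dict[str, int]:
    """Read chromosome lengths from a two-column 'chrom<TAB>length' file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            lengths[chrom] = int(size)
    return lengths
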