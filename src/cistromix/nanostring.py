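"""Two-stage digital-count normalization and expression transforms.

Counts from an nCounter-style assay are normalised in two stages:

1. *Positive controls* — each sample is scaled so its geometric mean of the
   spike-in positive-control probes matches the cross-sample arithmetic mean
   of those geometric means (removes lane/technical efficiency differences).
2. *Reference genes* — the same factor construction over the housekeeping
   reference probes on the stage-1 output (removes RNA content differences).

Both per-sample factors are recorded; for endogenous and reference probes
normalised = raw x pc_factor x ref_factor, while spike-in positive controls
are scaled by the positive-control factor only (they are fully corrected by
stage 1, which is what makes the whole procedure exactly idempotent: on
re-application every factor is 1).  The target of each stage is the
cross-sample mean rather than a fixed constant, so the output stays on the
input count scale.  Zero counts entering a geometric mean are floored to 1
with a logged warning; endogenous zeros are left at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PROBE_CLASSES = ("endogenous", "positive_control", "reference")

#: reference probe sets used for the two assay designs
CELL_LINE_REFERENCE_GENES = ("ALAS1", "GAPDH", "HMBS")
CLINICAL_REFERENCE_GENES = ("SDHA", "ALAS1", "GAPDH", "HMBS", "PARPBP")


@dataclass
class CountMatrix:
    """Probes x samples counts with probe classes and sample metadata."""

    counts: pd.DataFrame  # index: probe ids, columns: sample ids
    probe_class: pd.Series  # probe id -> one of PROBE_CLASSES
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        missing = self.counts.index.difference(self.probe_class.index)
        if len(missing):
            raise ValueError(f"probes without a class: {list(missing)[:5]}")

    def probes_of_class(self, cls: str) -> list[str]:
        ids = self.probe_class[self.probe_class == cls].index
        return [p for p in self.counts.index if p in set(ids)]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[self.probes_of_class("endogenous")]


@dataclass
class NormalisedMatrix:
    counts: pd.DataFrame
    probe_class: pd.Series
    sample_meta: pd.DataFrame
    pc_factor: pd.Series  # per-sample positive-control scale factor
    ref_factor: pd.Series  # per-sample reference-gene scale factor

    @property
    def endogenous(self) -> pd.DataFrame:
        ids = self.probe_class[self.probe_class == "endogenous"].index
        return self.counts.loc[[p for p in self.counts.index if p in set(ids)]]


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log v)) of strictly positive values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty input")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _floored(block: pd.DataFrame, what: str) -> pd.DataFrame:
    n_zero = int((block.values == 0).sum())
    if n_zero:
        log.warning("flooring %d zero %s counts to 1 for geometric mean", n_zero, what)
        block = block.where(block > 0, 1.0)
    return block


def _stage_factors(block: pd.DataFrame, what: str) -> pd.Series:
    """Per-sample factor = mean-of-geomeans / this sample's geomean."""
    block = _floored(block.astype(float), what)
    geomeans = np.exp(np.log(block).mean(axis=0))
    if (geomeans <= 0).any():
        bad = geomeans.index[geomeans <= 0][0]
        raise ValueError(f"sample {bad!r}: {what} geometric mean is zero")
    return geomeans.mean() / geomeans


def normalise(
    counts: CountMatrix, ref_probe_ids: Optional[Sequence[str]] = None
) -> NormalisedMatrix:
    """Positive-control then reference-gene normalization.

    ``ref_probe_ids`` defaults to every probe of class "reference" in the
    matrix (e.g. ALAS1/GAPDH/HMBS for cell-line CodeSets, plus SDHA and
    PARPBP for the clinical design).
    """
    if ref_probe_ids is None:
        ref_probe_ids = counts.probes_of_class("reference")
    pc_ids = counts.probes_of_class("positive_control")
    if not pc_ids:
        raise ValueError("no positive-control probes in matrix")
    if not ref_probe_ids:
        raise ValueError("no reference probes given")
    missing = [p for p in ref_probe_ids if p not in counts.counts.index]
    if missing:
        raise ValueError(f"reference probes absent from matrix: {missing}")

    raw = counts.counts.astype(float)
    pc_factor = _stage_factors(raw.loc[pc_ids], "positive-control")
    stage1 = raw.mul(pc_factor, axis=1)
    ref_factor = _stage_factors(stage1.loc[list(ref_probe_ids)], "reference-gene")
    # reference factors correct RNA content; the spike-ins are already fully
    # corrected by stage 1 and stay on the positive-control scale
    normalised = stage1.mul(ref_factor, axis=1)
    normalised.loc[pc_ids] = stage1.loc[pc_ids]
    return NormalisedMatrix(
        counts=normalised,
        probe_class=counts.probe_class,
        sample_meta=counts.sample_meta,
        pc_factor=pc_factor,
        ref_factor=ref_factor,
    )


def zscore_by_gene(m: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples: (x - mean) / sd with ddof=1.

    Raises on zero-variance genes (their z-score is undefined); callers that
    want to tolerate them should drop constant rows first.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    sd = m.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"zero-variance genes: {constant}")
    return m.sub(m.mean(axis=1), axis=0).div(sd, axis=0)


def fold_to_normal_median(
    m: pd.DataFrame, normal_sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Express each value relative to the gene's median over normal samples.

    The normal median maps to 1, so a tumour value of 2 means twofold the
    typical normal level.
    """
    normal_ids = [s for s in normal_sample_ids if s in m.columns]
    if not normal_ids:
        raise ValueError("no normal samples present in matrix")
    med = m[normal_ids].median(axis=1)
    zero = med[med <= 0].index.tolist()
    if zero:
        raise ValueError(f"zero normal median for genes: {zero}")
    return m.div(med, axis=0)


# ---------------------------------------------------------------------------
# Count matrix I/O: CSV with probe_id, probe_class, then one sample per
# column; sample metadata CSV keyed by sample id.
# ---------------------------------------------------------------------------


def read_counts(counts_path: str, meta_path: Optional[str] = None) -> CountMatrix:
    df = pd.read_csv(counts_path, comment="#")
    if df.columns[0] != "probe_id" or df.columns[1] != "probe_class":
        raise ValueError(
            "count CSV must start with probe_id and probe_class columns"
        )
    probe_class = df.set_index("probe_id")["probe_class"]
    counts = df.set_index("probe_id").drop(columns=["probe_class"])
    meta = pd.DataFrame(index=counts.columns)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, comment="#").set_index("sample_id")
        meta = meta.loc[[s for s in counts.columns if s in meta.index]]
    return CountMatrix(counts, probe_class, meta)


def write_counts(m: CountMatrix | NormalisedMatrix, path: str, header_lines=()) -> None:
    out = m.counts.copy()
    out.insert(0, "probe_class", m.probe_class.reindex(out.index))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index_label="probe_id")
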