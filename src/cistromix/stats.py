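"""Anchor-gene correlation ranking, clustering, and group statistics.

This module covers the expression-side analyses: ranking genes by Pearson
correlation with an anchor gene (FOXM1 in the motivating application)
across tumour samples, unsupervised hierarchical clustering with a
correlation metric, Mann-Whitney tumour/normal and stage-stratified
contrasts, SPSS-style boxplot summaries, the high/low anchor-expression
partition of tumours, pooled-variance t tests for siRNA knockdowns, and the
two-knockdown Venn partition with sign-discordance flags.

No multiple-testing correction is applied anywhere; p-values are reported
raw with '**' (p < 0.01) and '*' (p < 0.05) marks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def significance_mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationResult:
    gene_id: str
    r: float
    passes_threshold: bool


@dataclass
class GroupComparison:
    gene_id: str
    group_a_label: str
    group_b_label: str
    statistic: float
    p_value: float
    fold_change: float
    test: str = "mannwhitney"

    @property
    def significance_mark(self) -> str:
        return significance_mark(self.p_value)


@dataclass
class BoxplotSummary:
    gene_id: str
    group: str
    q1: float
    median: float
    q3: float
    outliers: list[float] = field(default_factory=list)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def log2_counts(m: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform, the standard scale for expression correlation."""
    return np.log2(m.astype(float) + 1.0)


def drop_constant_genes(
    m: pd.DataFrame, rel_tol: float = 1e-12
) -> tuple[pd.DataFrame, list[str]]:
    """Split off genes whose variation is zero up to numerical noise.

    A gene is constant when its sd is below ``rel_tol`` times its mean
    magnitude; the tolerance absorbs float rounding introduced by
    normalization factors.  Returns (kept matrix, dropped gene ids).
    """
    sd = m.std(axis=1, ddof=1)
    scale = m.abs().mean(axis=1) + 1e-300
    constant = sd.index[(sd == 0) | (sd / scale < rel_tol)].tolist()
    return m.drop(index=constant), constant


def anchor_correlation(
    m: pd.DataFrame, anchor: str, threshold: float = 0.7
) -> tuple[list[CorrelationResult], list[str]]:
    """Pearson correlation of every gene with the anchor gene.

    Returns per-gene results (genes flagged at r strictly > ``threshold``)
    plus the sample ids sorted by ascending anchor expression — the order
    used to lay out correlation heatmaps.  Zero-variance genes have no
    defined correlation and are omitted with a warning.
    """
    if anchor not in m.index:
        raise ValueError(f"anchor gene {anchor!r} not in matrix")
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation ranking")
    x = m.loc[anchor].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance")
    results = []
    for gene in m.index:
        y = m.loc[gene].to_numpy(dtype=float)
        if np.std(y) == 0:
            log.warning("gene %s has zero variance; correlation undefined", gene)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        results.append(CorrelationResult(gene, r, bool(r > threshold)))
    sample_order = list(m.columns[np.argsort(x, kind="stable")])
    return results, sample_order


def correlation_distance(m: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows of ``m``."""
    sd = m.std(axis=1, ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise ValueError(f"zero-variance items: {bad}")
    corr = np.corrcoef(m.to_numpy(dtype=float))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative rounding before squareform
    dist = np.clip(dist, 0.0, None)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    m: pd.DataFrame, axis: str = "genes"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering with 1 - Pearson distance, average linkage.

    ``axis`` selects whether genes (rows) or samples (columns) are
    clustered.  Items are pre-sorted by id so ties resolve
    deterministically.  Returns the scipy linkage matrix and the leaf order.
    """
    if axis == "samples":
        m = m.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'samples'")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    m = m.loc[sorted(m.index)]
    condensed = correlation_distance(m)
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [m.index[i] for i in leaves]


def mannwhitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    gene_id: str = "",
    group_a_label: str = "a",
    group_b_label: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two sample groups.

    Exact enumeration of the U distribution when n_a + n_b <= 12 and there
    are no ties; tie-corrected normal approximation otherwise.  The fold
    change for tissue contrasts is the ratio of group medians (b over a).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.ptp(pooled) == 0:
        # fully degenerate: every observation identical
        u, p = a.size * b.size / 2.0, 1.0
    elif a.size + b.size <= 12 and not has_ties:
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    med_a = float(np.median(a))
    fold = float(np.median(b) / med_a) if med_a != 0 else float("nan")
    return GroupComparison(
        gene_id, group_a_label, group_b_label, float(u), float(p), fold,
        test="mannwhitney",
    )


def boxplot_summary(
    values: Sequence[float], gene_id: str = "", group: str = ""
) -> BoxplotSummary:
    """Quartiles by linear interpolation plus 1.5 x IQR outlier flags.

    Outliers are values strictly beyond q3 + 1.5*IQR or q1 - 1.5*IQR, the
    convention used for clinical-sample boxplots.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("boxplot summary needs at least 4 values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted(float(v) for v in arr[(arr < lo) | (arr > hi)])
    return BoxplotSummary(gene_id, group, float(q1), float(med), float(q3), outliers)


def partition_foxm1(
    tumour_values: pd.Series | Sequence[float],
    normal_values: Sequence[float],
) -> pd.Series:
    """Label tumour samples 'high' or 'low' relative to the normal group.

    'high' requires the value to exceed BOTH mean + 2 sd of the normals and
    twice the normal mean (sample sd, strict inequalities); everything else
    is 'low'.  Both criteria scale with the data, so the labels are
    invariant under multiplying all values by a positive constant.
    """
    normals = np.asarray(normal_values, dtype=float)
    if normals.size < 2:
        raise ValueError("need at least 2 normal values")
    mean, sd = normals.mean(), normals.std(ddof=1)
    tumours = pd.Series(tumour_values, dtype=float)
    high = (tumours > mean + 2 * sd) & (tumours > 2 * mean)
    return high.map({True: "high", False: "low"})


def knockdown_test(
    control_replicates: Sequence[float],
    treated_replicates: Sequence[float],
    gene_id: str = "",
    control_label: str = "siNTC",
    treated_label: str = "treated",
) -> GroupComparison:
    """Unpaired two-tailed pooled-variance (equal-variance) t test.

    Fold change is mean(treated) / mean(control) with the control taken
    as 1; use log2 of it for knockdown heatmaps.
    """
    c = np.asarray(control_replicates, dtype=float)
    t = np.asarray(treated_replicates, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValueError("need at least 2 replicates per arm")
    if c.std(ddof=1) == 0 and t.std(ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    stat, p = sps.ttest_ind(c, t, equal_var=True)
    mean_c = c.mean()
    fold = float(t.mean() / mean_c) if mean_c != 0 else float("nan")
    return GroupComparison(
        gene_id, control_label, treated_label, float(stat), float(p), fold,
        test="ttest",
    )


@dataclass
class VennResult:
    a_only: set[str]
    b_only: set[str]
    shared: set[str]
    discordant: set[str]


def venn_overlap(
    set_a: Iterable[tuple[str, str]], set_b: Iterable[tuple[str, str]]
) -> VennResult:
    """Three-way partition of two (gene, direction) sets.

    Directions are 'up'/'down' (or any two labels); genes present in both
    sets with opposite directions are flagged as discordant.
    """
    dir_a = dict(set_a)
    dir_b = dict(set_b)
    shared = set(dir_a) & set(dir_b)
    return VennResult(
        a_only=set(dir_a) - shared,
        b_only=set(dir_b) - shared,
        shared=shared,
        discordant={g for g in shared if dir_a[g] != dir_b[g]},
    )


def group_statistics(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    contrast_column: str,
    group_a: str,
    group_b: str,
) -> list[GroupComparison]:
    """Mann-Whitney contrast of every gene between two metadata groups."""
    if contrast_column not in meta.columns:
        raise ValueError(f"metadata column {contrast_column!r} missing")
    ids_a = meta.index[meta[contrast_column] == group_a]
    ids_b = meta.index[meta[contrast_column] == group_b]
    ids_a = [s for s in ids_a if s in m.columns]
    ids_b = [s for s in ids_b if s in m.columns]
    if not ids_a or not ids_b:
        raise ValueError(f"empty group for contrast {group_a!r} vs {group_b!r}")
    return [
        mannwhitney(m.loc[g, ids_a], m.loc[g, ids_b], g, group_a, group_b)
        for g in m.index
    ]
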