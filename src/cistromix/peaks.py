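"""Replicate consensus, pooled high-sensitivity filtering, and cross-cell-type
shared/unique classification of peak sets.

The consensus rule mirrors how high-confidence binding regions are derived
from two ChIP-seq replicates: two peaks overlap when at least ``min_frac``
of the smaller peak lies within the larger one, and an overlapping pair
qualifies when at least ONE of the two peaks has FDR < ``max_fdr`` (percent)
and tag density > ``min_td``.  Qualifying pairs are merged by connected
components so a chain of mutually overlapping peaks yields one region.
All threshold comparisons are strict (<, >).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import GenomicInterval, Peak, PeakSet, overlap_fraction


@dataclass
class ConsensusResult:
    """Merged replicate-supported regions plus supporting-peak provenance."""

    regions: PeakSet
    support: list[dict[str, list[str]]] = field(default_factory=list)

    @property
    def n_high_confidence(self) -> int:
        return len(self.regions)


@dataclass
class SetComparison:
    """Shared/unique partition of two peak sets under the overlap rule."""

    shared_a: PeakSet
    shared_b: PeakSet
    unique_a: PeakSet
    unique_b: PeakSet


def filter_high_sensitivity(
    peaks: PeakSet, max_fdr: float = 10.0, min_td: float = 30.0
) -> PeakSet:
    """Keep peaks with fdr < max_fdr AND tag_density > min_td (both strict).

    With the defaults this is the high-sensitivity filter applied to peaks
    re-called from the pooled ("combined reads") replicate data.
    """
    if max_fdr < 0 or min_td < 0:
        raise ValueError("thresholds must be non-negative")
    kept = [p for p in peaks if p.fdr < max_fdr and p.tag_density > min_td]
    return PeakSet(kept, label=peaks.label)


def _passes_gate(p: Peak, max_fdr: float, min_td: float) -> bool:
    return p.fdr < max_fdr and p.tag_density > min_td


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _overlap_candidates(tree_by_chrom: dict[str, IntervalTree], peak: Peak):
    tree = tree_by_chrom.get(peak.chrom)
    if tree is None:
        return []
    return tree.overlap(peak.start, peak.end)


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, idx)
    return trees


def replicate_consensus(
    rep1: PeakSet,
    rep2: PeakSet,
    min_frac: float = 0.5,
    max_fdr: float = 10.0,
    min_td: float = 15.0,
) -> ConsensusResult:
    """Derive high-confidence consensus regions from two replicate peak sets.

    Three steps: (1) build the bipartite overlap graph with an edge whenever
    ``overlap_fraction >= min_frac``; (2) keep edges where at least one
    endpoint has fdr < max_fdr and tag_density > min_td; (3) every connected
    component of surviving edges containing peaks from both replicates
    becomes one consensus region — the union interval of its members, with
    the summit taken from the member of highest tag density.
    """
    if len(rep1) == 0 or len(rep2) == 0:
        raise ValueError("consensus undefined: replicate peak set is empty")
    peaks1 = list(rep1)
    peaks2 = list(rep2)
    n1 = len(peaks1)
    uf = _UnionFind(n1 + len(peaks2))
    has_edge = [False] * (n1 + len(peaks2))
    trees2 = _build_trees(rep2)
    for i, p1 in enumerate(peaks1):
        for iv in _overlap_candidates(trees2, p1):
            j = iv.data
            p2 = peaks2[j]
            if overlap_fraction(p1, p2) < min_frac:
                continue
            if _passes_gate(p1, max_fdr, min_td) or _passes_gate(p2, max_fdr, min_td):
                uf.union(i, n1 + j)
                has_edge[i] = True
                has_edge[n1 + j] = True

    components: dict[int, dict[str, list[int]]] = {}
    for k in range(n1 + len(peaks2)):
        if not has_edge[k]:
            continue
        root = uf.find(k)
        comp = components.setdefault(root, {"rep1": [], "rep2": []})
        comp["rep1" if k < n1 else "rep2"].append(k)

    regions: list[Peak] = []
    support: list[dict[str, list[str]]] = []
    rows = []
    for comp in components.values():
        members = [peaks1[i] for i in comp["rep1"]] + [
            peaks2[k - n1] for k in comp["rep2"]
        ]
        if not comp["rep1"] or not comp["rep2"]:
            continue  # edge gating guarantees both sides, but keep the invariant explicit
        chrom = members[0].chrom
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        best = max(members, key=lambda m: (m.tag_density, m.peak_id))
        rows.append(
            (
                chrom,
                start,
                end,
                best.summit,
                min(m.fdr for m in members),
                best.tag_density,
                {
                    "rep1": sorted(peaks1[i].peak_id for i in comp["rep1"]),
                    "rep2": sorted(peaks2[k - n1].peak_id for k in comp["rep2"]),
                },
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    for idx, (chrom, start, end, summit, fdr, td, supp) in enumerate(rows, start=1):
        regions.append(
            Peak(
                GenomicInterval(chrom, start, end),
                summit,
                fdr,
                td,
                peak_id=f"consensus_{idx}",
                source="consensus",
            )
        )
        support.append(supp)
    return ConsensusResult(PeakSet(regions, label="consensus"), support)


def compare_peak_sets(a: PeakSet, b: PeakSet, min_frac: float = 0.5) -> SetComparison:
    """Partition each set into peaks shared with (>= min_frac overlap partner)
    or unique to the other set.  Counts are exhaustive and disjoint:
    |shared| + |unique| equals the set size on each side.
    """

    def split(src: PeakSet, other: PeakSet) -> tuple[list[Peak], list[Peak]]:
        trees = _build_trees(other)
        others = list(other)
        shared, unique = [], []
        for p in src:
            hit = any(
                overlap_fraction(p, others[iv.data]) >= min_frac
                for iv in _overlap_candidates(trees, p)
            )
            (shared if hit else unique).append(p)
        return shared, unique

    sa, ua = split(a, b)
    sb, ub = split(b, a)
    return SetComparison(
        shared_a=PeakSet(sa, label=f"{a.label}_shared"),
        shared_b=PeakSet(sb, label=f"{b.label}_shared"),
        unique_a=PeakSet(ua, label=f"{a.label}_unique"),
        unique_b=PeakSet(ub, label=f"{b.label}_unique"),
    )
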