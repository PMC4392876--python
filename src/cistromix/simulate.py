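"""Seeded generators for peak, tag and count data with known ground truth.

Every generator is a pure function of its configuration: the same seed
yields byte-identical outputs.  The defaults emulate the study design the
analysis modules were built for — two ChIP-seq peak replicates with
controlled overlap fractions straddling the 50% consensus cut-off and
FDR/tag-density marginals straddling the significance gate; summit-centred
Gaussian tag enrichment over a uniform Poisson background; and an
nCounter-style count matrix for 24 normal vs 58 tumour samples with a
FOXM1-like anchor gene, a planted correlated gene block, anti-correlated
genes, constant-up-to-CV reference probes and a geometric positive-control
ladder.

Counts are drawn log-normal and rounded: digital counts of biological
replicates are over-dispersed relative to Poisson, and a log-normal noise
model captures that with a single spread parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, Peak, PeakSet
from .density import TagPositions
from .nanostring import CLINICAL_REFERENCE_GENES, CountMatrix


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PeakPlan:
    n_consensus_pairs: int = 30  # overlap >= 0.5 and gate passed -> must survive
    n_low_overlap_pairs: int = 10  # overlap < 0.5 -> must not survive
    n_gate_fail_pairs: int = 10  # overlap ok but both peaks fail the FDR/TD gate
    n_unique_per_set: int = 15  # no partner in the other replicate
    min_length: int = 200
    max_length: int = 800
    surviving_overlap: tuple[float, float] = (0.55, 0.95)
    failing_overlap: tuple[float, float] = (0.05, 0.45)
    passing_fdr: tuple[float, float] = (0.0, 9.5)
    passing_td: tuple[float, float] = (16.0, 100.0)
    failing_fdr: tuple[float, float] = (10.5, 40.0)
    failing_td: tuple[float, float] = (1.0, 14.0)


@dataclass
class TagPlan:
    tags_per_peak: float = 200.0
    enrichment_sd: float = 100.0  # bp spread of summit-centred enrichment
    background_rate: float = 1e-4  # tags per bp of genome


@dataclass
class ExpressionPlan:
    n_normal: int = 24
    n_tumour: int = 58
    anchor_gene: str = "FOXM1"
    anchor_base_count: float = 400.0
    anchor_tumour_fold: float = 4.0
    n_correlated: int = 20
    planted_r: float = 0.8
    n_anticorrelated: int = 5
    anti_r: float = -0.6
    n_null: int = 10
    base_count: float = 500.0
    log_noise_sd: float = 0.5  # natural-log sd of endogenous probes
    reference_genes: tuple[str, ...] = tuple(CLINICAL_REFERENCE_GENES)
    reference_base_count: float = 800.0
    reference_cv: float = 0.05
    positive_control_ladder: tuple[float, ...] = (31, 125, 500, 2000, 8000, 32000)
    technical_sd: float = 0.15  # per-sample lane factor (all probes)
    content_sd: float = 0.10  # per-sample RNA content factor (non-spike-ins)
    n_late_stage: int = 32  # of the tumour samples (rest early)
    stage_folds: dict[str, float] = field(
        default_factory=lambda: {"LIN54": 0.5, "UHRF1": 1.8}
    )
    tumour_folds: dict[str, float] = field(default_factory=dict)


@dataclass
class KnockdownPlan:
    arms: tuple[str, ...] = ("siNTC", "siFOXM1", "siLIN9")
    n_replicates: int = 3
    base_count: float = 1000.0
    log2_noise_sd: float = 0.15
    # per-gene log2 fold effects for each non-control arm
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "CCNB1": {"siFOXM1": -1.2, "siLIN9": -1.0},
            "CENPF": {"siFOXM1": -1.0, "siLIN9": -0.8},
            "UBE2C": {"siFOXM1": -0.9, "siLIN9": -0.9},
            "PLK1": {"siFOXM1": -1.1, "siLIN9": -0.7},
            "UHRF1": {"siFOXM1": -1.3, "siLIN9": -0.6},
            "NDE1": {"siFOXM1": -1.0, "siLIN9": -0.3},
            "HMGB3": {"siFOXM1": -0.4, "siLIN9": -1.2},
            "CDKN3": {"siFOXM1": -1.2, "siLIN9": -0.2},
            "ARHGAP19": {"siFOXM1": -0.8, "siLIN9": 0.8},
            "AGFG2": {"siFOXM1": 0.0, "siLIN9": 0.0},
            "CCDC85C": {"siFOXM1": 0.0, "siLIN9": 0.0},
            "SNX5": {"siFOXM1": -0.6, "siLIN9": -0.5},
        }
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )
    peaks: PeakPlan = field(default_factory=PeakPlan)
    tags: TagPlan = field(default_factory=TagPlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    knockdown: KnockdownPlan = field(default_factory=KnockdownPlan)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls()
        for key in ("seed", "genome"):
            if key in d:
                setattr(cfg, key, d[key])
        for key, sub in (
            ("peaks", cfg.peaks),
            ("tags", cfg.tags),
            ("expression", cfg.expression),
            ("knockdown", cfg.knockdown),
        ):
            for k, v in d.get(key, {}).items():
                if not hasattr(sub, k):
                    raise ValueError(f"unknown config key {key}.{k}")
                setattr(sub, k, v)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _stream_rng(seed: int, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream_id]))


# ---------------------------------------------------------------------------
# peak replicates
# ---------------------------------------------------------------------------


def simulate_peak_replicates(
    cfg: SimulationConfig,
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Two replicate peak sets with a truth table of planned pair outcomes.

    The truth table has one row per planned peak (or pair) recording the
    realised overlap fraction, whether the FDR/TD gate passes, and whether
    the pair must survive replicate consensus.  Planned pairs are placed on
    non-overlapping genomic slots, so planned outcomes are exact.
    """
    plan = cfg.peaks
    rng = _stream_rng(cfg.seed, 1)
    total_slots = (
        plan.n_consensus_pairs
        + plan.n_low_overlap_pairs
        + plan.n_gate_fail_pairs
        + 2 * plan.n_unique_per_set
    )
    if total_slots == 0:
        raise ValueError("peak plan is empty")
    chroms = sorted(cfg.genome)
    stride = 4 * plan.max_length + 2000
    capacity = sum(max(0, (L - stride) // stride) for L in cfg.genome.values())
    if capacity < total_slots:
        raise ValueError(
            f"infeasible peak plan: {total_slots} slots needed, genome fits {capacity}"
        )
    slots = []
    for chrom in chroms:
        n_here = max(0, (cfg.genome[chrom] - stride) // stride)
        slots.extend((chrom, stride // 2 + i * stride) for i in range(n_here))
    slots = slots[:total_slots]
    rng.shuffle(slots)

    rep1: list[Peak] = []
    rep2: list[Peak] = []
    rows = []

    def draw_len() -> int:
        return int(rng.integers(plan.min_length, plan.max_length + 1))

    def draw_marginals(passing: bool) -> tuple[float, float]:
        if passing:
            return (
                float(rng.uniform(*plan.passing_fdr)),
                float(rng.uniform(*plan.passing_td)),
            )
        return (
            float(rng.uniform(*plan.failing_fdr)),
            float(rng.uniform(*plan.failing_td)),
        )

    def make_peak(chrom, start, length, fdr, td, pid, source) -> Peak:
        summit = start + int(rng.integers(0, length))
        return Peak(
            GenomicInterval(chrom, start, start + length), summit, fdr, td, pid, source
        )

    def add_pair(kind: str, slot, idx: int) -> None:
        chrom, anchor = slot
        l1, l2 = draw_len(), draw_len()
        lmin = min(l1, l2)
        if kind == "low_overlap":
            frac_target = rng.uniform(*plan.failing_overlap)
        else:
            frac_target = rng.uniform(*plan.surviving_overlap)
        inter = int(round(frac_target * lmin))
        start1 = anchor
        start2 = start1 + l1 - inter
        if start2 + l2 >= cfg.genome[chrom]:
            start2 = start1 - (l2 - inter)  # fall back to left placement
        inter_real = max(
            0, min(start1 + l1, start2 + l2) - max(start1, start2)
        )
        frac = inter_real / lmin if lmin else 0.0
        if kind == "gate_fail":
            fdr1, td1 = draw_marginals(False)
            fdr2, td2 = draw_marginals(False)
        elif kind == "consensus":
            # at least one replicate passes; the other is a coin flip
            which = rng.integers(0, 3)  # 0: rep1, 1: rep2, 2: both
            fdr1, td1 = draw_marginals(which in (0, 2))
            fdr2, td2 = draw_marginals(which in (1, 2))
        else:  # low_overlap: marginals irrelevant, draw passing ones
            fdr1, td1 = draw_marginals(True)
            fdr2, td2 = draw_marginals(True)
        p1 = make_peak(chrom, start1, l1, fdr1, td1, f"r1_{kind}_{idx}", "rep1")
        p2 = make_peak(chrom, start2, l2, fdr2, td2, f"r2_{kind}_{idx}", "rep2")
        rep1.append(p1)
        rep2.append(p2)
        gate = (fdr1 < 10 and td1 > 15) or (fdr2 < 10 and td2 > 15)
        rows.append(
            {
                "kind": kind,
                "rep1_peak_id": p1.peak_id,
                "rep2_peak_id": p2.peak_id,
                "overlap_fraction": frac,
                "gate_pass": gate,
                "expected_consensus": frac >= 0.5 and gate,
            }
        )

    slot_iter = iter(slots)
    for i in range(plan.n_consensus_pairs):
        add_pair("consensus", next(slot_iter), i)
    for i in range(plan.n_low_overlap_pairs):
        add_pair("low_overlap", next(slot_iter), i)
    for i in range(plan.n_gate_fail_pairs):
        add_pair("gate_fail", next(slot_iter), i)
    for i in range(plan.n_unique_per_set):
        chrom, anchor = next(slot_iter)
        fdr, td = draw_marginals(True)
        rep1.append(make_peak(chrom, anchor, draw_len(), fdr, td, f"r1_uniq_{i}", "rep1"))
        rows.append(
            {
                "kind": "unique_rep1",
                "rep1_peak_id": f"r1_uniq_{i}",
                "rep2_peak_id": "",
                "overlap_fraction": 0.0,
                "gate_pass": fdr < 10 and td > 15,
                "expected_consensus": False,
            }
        )
    for i in range(plan.n_unique_per_set):
        chrom, anchor = next(slot_iter)
        fdr, td = draw_marginals(True)
        rep2.append(make_peak(chrom, anchor, draw_len(), fdr, td, f"r2_uniq_{i}", "rep2"))
        rows.append(
            {
                "kind": "unique_rep2",
                "rep1_peak_id": "",
                "rep2_peak_id": f"r2_uniq_{i}",
                "overlap_fraction": 0.0,
                "gate_pass": fdr < 10 and td > 15,
                "expected_consensus": False,
            }
        )

    truth = pd.DataFrame(rows)
    return (
        PeakSet(rep1, label="rep1").sorted(),
        PeakSet(rep2, label="rep2").sorted(),
        truth,
    )


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------


def simulate_tags(cfg: SimulationConfig, peaks: PeakSet) -> TagPositions:
    """Poisson background plus Gaussian summit-centred enrichment."""
    plan = cfg.tags
    rng = _stream_rng(cfg.seed, 2)
    positions: dict[str, list[np.ndarray]] = {c: [] for c in cfg.genome}
    for chrom, length in sorted(cfg.genome.items()):
        n_bg = rng.poisson(plan.background_rate * length)
        if n_bg:
            positions[chrom].append(rng.integers(0, length, size=n_bg))
    for p in peaks.sorted():
        if p.chrom not in cfg.genome:
            raise ValueError(f"peak {p.peak_id} on chromosome absent from genome")
        n = rng.poisson(plan.tags_per_peak)
        if n:
            pos = rng.normal(p.summit, plan.enrichment_sd, size=n)
            pos = np.clip(np.rint(pos), 0, cfg.genome[p.chrom] - 1).astype(np.int64)
            positions[p.chrom].append(pos)
    return {
        c: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
        for c, parts in positions.items()
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """nCounter-style count matrix plus per-probe ground-truth table.

    The anchor gene is elevated in the tumour group; a planted block of
    genes tracks the anchor's realised (log-scale) expression with the
    configured Pearson correlation; anti-correlated genes track it with a
    negative coefficient; null genes are independent noise.  The planted
    correlation is defined on the log-expression scale, where expression
    correlation analyses operate (Pearson r of raw skewed counts is
    systematically attenuated relative to the log scale); with ``r = 1``
    the block is an exact monotone function of the anchor.  Per-sample
    technical (lane) factors multiply every probe and are removed by the
    positive-control normalization stage; per-sample content factors
    multiply the non-spike-in probes and are removed by the reference-gene
    stage.
    """
    plan = cfg.expression
    if plan.n_normal < 2:
        raise ValueError("need at least 2 normal samples")
    rng = _stream_rng(cfg.seed, 3)
    n = plan.n_normal + plan.n_tumour
    sample_ids = [f"N{i + 1:02d}" for i in range(plan.n_normal)] + [
        f"T{i + 1:02d}" for i in range(plan.n_tumour)
    ]
    is_tumour = np.array([0] * plan.n_normal + [1] * plan.n_tumour)

    technical = np.exp(rng.normal(0, plan.technical_sd, size=n))
    content = np.exp(rng.normal(0, plan.content_sd, size=n))

    # anchor on the natural-log scale, tumour group shifted by log(fold)
    anchor_log = (
        np.log(plan.anchor_base_count)
        + np.log(plan.anchor_tumour_fold) * is_tumour
        + rng.normal(0, plan.log_noise_sd, size=n)
    )
    anchor_z = (anchor_log - anchor_log.mean()) / anchor_log.std()

    rows: dict[str, np.ndarray] = {}
    truth_rows = []

    def planted_gene(name: str, r: float, kind: str) -> None:
        eps = rng.normal(0, 1, size=n)
        z = r * anchor_z + np.sqrt(1 - r**2) * eps
        log_expr = np.log(plan.base_count) + plan.log_noise_sd * z
        rows[name] = np.exp(log_expr)
        truth_rows.append(
            {"probe_id": name, "kind": kind, "planted_r": r, "tumour_fold": np.nan}
        )

    rows[plan.anchor_gene] = np.exp(anchor_log)
    truth_rows.append(
        {
            "probe_id": plan.anchor_gene,
            "kind": "anchor",
            "planted_r": 1.0,
            "tumour_fold": plan.anchor_tumour_fold,
        }
    )
    for i in range(plan.n_correlated):
        planted_gene(f"COR{i + 1:02d}", plan.planted_r, "correlated")
    for i in range(plan.n_anticorrelated):
        planted_gene(f"ANT{i + 1:02d}", plan.anti_r, "anticorrelated")
    for i in range(plan.n_null):
        log_expr = np.log(plan.base_count) + rng.normal(0, plan.log_noise_sd, size=n)
        rows[f"NUL{i + 1:02d}"] = np.exp(log_expr)
        truth_rows.append(
            {
                "probe_id": f"NUL{i + 1:02d}",
                "kind": "null",
                "planted_r": 0.0,
                "tumour_fold": np.nan,
            }
        )
    for gene, fold in plan.tumour_folds.items():
        log_expr = (
            np.log(plan.base_count)
            + np.log(fold) * is_tumour
            + rng.normal(0, plan.log_noise_sd, size=n)
        )
        rows[gene] = np.exp(log_expr)
        truth_rows.append(
            {"probe_id": gene, "kind": "tumour_effect", "planted_r": 0.0,
             "tumour_fold": fold}
        )

    # stage labels: n_late_stage of the tumours are late T stage
    stage = np.array(["normal"] * plan.n_normal + ["early"] * plan.n_tumour, dtype=object)
    late_idx = plan.n_normal + rng.permutation(plan.n_tumour)[: plan.n_late_stage]
    stage[late_idx] = "late"
    late_mask = np.array([s == "late" for s in stage], dtype=float)
    for gene, fold in plan.stage_folds.items():
        log_expr = (
            np.log(plan.base_count)
            + np.log(fold) * late_mask
            + rng.normal(0, plan.log_noise_sd, size=n)
        )
        rows[gene] = np.exp(log_expr)
        truth_rows.append(
            {"probe_id": gene, "kind": "stage_effect", "planted_r": 0.0,
             "tumour_fold": fold}
        )

    probe_class = {}
    for name in rows:
        probe_class[name] = "endogenous"
        rows[name] = np.rint(rows[name] * content * technical)
    for name in plan.reference_genes:
        noise = np.exp(rng.normal(0, plan.reference_cv, size=n))
        rows[name] = np.rint(plan.reference_base_count * noise * content * technical)
        probe_class[name] = "reference"
        truth_rows.append(
            {"probe_id": name, "kind": "reference", "planted_r": 0.0,
             "tumour_fold": np.nan}
        )
    for i, level in enumerate(plan.positive_control_ladder):
        name = f"POS_{chr(ord('A') + i)}"
        rows[name] = np.rint(np.maximum(level * technical, 1.0))
        probe_class[name] = "positive_control"
        truth_rows.append(
            {"probe_id": name, "kind": "positive_control", "planted_r": 0.0,
             "tumour_fold": np.nan}
        )

    counts = pd.DataFrame(rows, index=sample_ids).T
    meta = pd.DataFrame(
        {
            "group": ["normal"] * plan.n_normal + ["OAC"] * plan.n_tumour,
            "t_stage": stage,
            "nodal_met": np.where(
                (is_tumour == 1) & (rng.random(n) < 0.6), "present", "absent"
            ),
            "distant_met": np.where(
                (is_tumour == 1) & (rng.random(n) < 0.3), "present", "absent"
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta.loc[meta["group"] == "normal", ["nodal_met", "distant_met"]] = "absent"
    truth = pd.DataFrame(truth_rows).set_index("probe_id")
    cm = CountMatrix(counts, pd.Series(probe_class, name="probe_class"), meta)
    return cm, truth


# ---------------------------------------------------------------------------
# knockdown
# ---------------------------------------------------------------------------


def simulate_knockdown(cfg: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Replicated siRNA knockdown count matrix with per-arm ground truth.

    Columns are <arm>_rep<k>; the control arm is the first entry of
    ``plan.arms``.  Truth records each gene's planted log2 effect and
    direction per non-control arm.
    """
    plan = cfg.knockdown
    rng = _stream_rng(cfg.seed, 4)
    control = plan.arms[0]
    columns = [f"{arm}_rep{k + 1}" for arm in plan.arms for k in range(plan.n_replicates)]
    rows = {}
    truth_rows = []
    for gene, effects in plan.effects.items():
        values = []
        for arm in plan.arms:
            effect = 0.0 if arm == control else effects.get(arm, 0.0)
            noise = rng.normal(0, plan.log2_noise_sd, size=plan.n_replicates)
            values.append(plan.base_count * 2.0 ** (effect + noise))
        rows[gene] = np.rint(np.concatenate(values))
        for arm in plan.arms[1:]:
            effect = effects.get(arm, 0.0)
            truth_rows.append(
                {
                    "probe_id": gene,
                    "arm": arm,
                    "log2_effect": effect,
                    "direction": "up" if effect > 0 else ("down" if effect < 0 else "none"),
                }
            )
    probe_class = {g: "endogenous" for g in rows}
    for name in ("ALAS1", "GAPDH", "HMBS"):
        noise = np.exp(rng.normal(0, 0.05, size=len(columns)))
        rows[name] = np.rint(800.0 * noise)
        probe_class[name] = "reference"
    for i, level in enumerate((125, 2000, 32000)):
        name = f"POS_{chr(ord('A') + i)}"
        rows[name] = np.rint(np.full(len(columns), float(level)))
        probe_class[name] = "positive_control"
    counts = pd.DataFrame(rows, index=columns).T
    meta = pd.DataFrame(
        {
            "sirna": [c.rsplit("_rep", 1)[0] for c in columns],
            "replicate": [int(c.rsplit("_rep", 1)[1]) for c in columns],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    truth = pd.DataFrame(truth_rows)
    return CountMatrix(counts, pd.Series(probe_class, name="probe_class"), meta), truth
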