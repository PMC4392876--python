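"""End-to-end workflow drivers chaining the analysis modules.

Two workflows are provided: the *cistrome* workflow (replicate consensus,
cross-cell-type comparison, nearest-gene annotation, genomic feature
distribution and summit-centred tag density) and the *expression* workflow
(two-stage normalization, anchor-gene correlation ranking, hierarchical
clustering, tumour/normal group statistics and boxplot summaries).

Every output file begins with provenance comment lines recording the tool
version, a hash of the effective configuration and the seed; a timestamp
line is added unless the run is marked reproducible.  With identical
configuration and inputs a reproducible run is byte-identical.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .annotation import assign_nearest_gene, feature_distribution
from .core import read_genes, read_genome_lengths, read_peaks, write_peaks
from .density import density_matrix, mean_profile, order_rows_by_signal, read_tags
from .nanostring import (
    fold_to_normal_median,
    normalise,
    read_counts,
    write_counts,
    zscore_by_gene,
)
from .peaks import compare_peak_sets, replicate_consensus
from .stats import (
    anchor_correlation,
    boxplot_summary,
    drop_constant_genes,
    group_statistics,
    hierarchical_cluster,
    log2_counts,
)

log = logging.getLogger(__name__)

#: workflow defaults: the thresholds a bare invocation applies
DEFAULTS = {
    "min_frac": 0.5,
    "max_fdr": 10.0,
    "min_td": 15.0,
    "min_td_pooled": 30.0,
    "upstream": 5000,
    "downstream": 1000,
    "promoter_pad": 1000,
    "flank": 5000,
    "bin_size": 50,
    "correlation_threshold": 0.7,
    "alpha": 0.05,
    "alpha_strong": 0.01,
}


@dataclass
class RunConfig:
    """Flat configuration for a workflow run: paths + thresholds + seed."""

    workflow: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=lambda: dict(DEFAULTS))
    outdir: str = "."
    seed: int = 0
    reproducible: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        cfg.workflow = d.get("workflow", "")
        cfg.inputs = dict(d.get("inputs", {}))
        cfg.params = {**DEFAULTS, **d.get("params", {})}
        cfg.outdir = d.get("outdir", ".")
        cfg.seed = int(d.get("seed", 0))
        cfg.reproducible = bool(d.get("reproducible", False))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "workflow": self.workflow,
                "inputs": self.inputs,
                "params": self.params,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> list[str]:
        lines = [
            f"cistromix v{__version__} config={self.config_hash()} seed={self.seed}"
        ]
        if not self.reproducible:
            lines.append(f"generated {datetime.datetime.now().isoformat()}")
        return lines


def _write_table(df: pd.DataFrame, path: str, cfg: RunConfig, index: bool = False,
                 index_label: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        for line in cfg.provenance():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _require(cfg: RunConfig, stage: str, *keys: str) -> list[str]:
    paths = []
    for key in keys:
        path = cfg.inputs.get(key)
        if not path:
            raise RuntimeError(f"stage {stage}: missing input {key!r}")
        if not os.path.exists(path):
            raise RuntimeError(f"stage {stage}: input {key!r} not found: {path}")
        paths.append(path)
    return paths


def run_cistrome_workflow(cfg: RunConfig) -> dict[str, str]:
    """Consensus -> comparison -> annotation -> distribution -> density.

    Inputs: ``rep1``/``rep2`` replicate peak tables, ``other_set`` (the
    other cell type's peaks, compared against the consensus regions),
    ``genes`` (BED12/GTF), ``genome`` (chrom sizes), ``tags`` (single-bp
    BED).  Returns a mapping of output names to written paths.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    p = cfg.params
    outputs: dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise RuntimeError(f"stage {name}: {exc}") from exc

        return wrap

    rep1_path, rep2_path = _require(cfg, "consensus", "rep1", "rep2")
    rep1 = read_peaks(rep1_path)
    rep2 = read_peaks(rep2_path)
    consensus = stage("consensus")(
        lambda: replicate_consensus(
            rep1, rep2, p["min_frac"], p["max_fdr"], p["min_td"]
        )
    )
    out = os.path.join(cfg.outdir, "consensus.bed")
    write_peaks(consensus.regions, out, header_lines=cfg.provenance())
    outputs["consensus"] = out

    (other_path,) = _require(cfg, "compare", "other_set")
    other = read_peaks(other_path)
    comparison = stage("compare")(
        lambda: compare_peak_sets(consensus.regions, other, p["min_frac"])
    )
    for name, ps in (
        ("shared_a", comparison.shared_a),
        ("shared_b", comparison.shared_b),
        ("unique_a", comparison.unique_a),
        ("unique_b", comparison.unique_b),
    ):
        out = os.path.join(cfg.outdir, f"compare_{name}.bed")
        write_peaks(ps, out, header_lines=cfg.provenance())
        outputs[f"compare_{name}"] = out
    summary = pd.DataFrame(
        {
            "set": ["a", "b"],
            "total": [len(consensus.regions), len(other)],
            "shared": [len(comparison.shared_a), len(comparison.shared_b)],
            "unique": [len(comparison.unique_a), len(comparison.unique_b)],
        }
    )
    out = os.path.join(cfg.outdir, "compare_summary.tsv")
    _write_table(summary, out, cfg)
    outputs["compare_summary"] = out

    (genes_path,) = _require(cfg, "annotate", "genes")
    genes = read_genes(genes_path)
    annotations = stage("annotate")(
        lambda: assign_nearest_gene(
            consensus.regions,
            genes,
            int(p["upstream"]),
            int(p["downstream"]),
            int(p["promoter_pad"]),
        )
    )
    annot_df = pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in annotations],
            "gene_id": [a.gene_id or "" for a in annotations],
            "relation": [a.relation for a in annotations],
            "distance_to_tss": [
                "" if a.distance_to_tss is None else a.distance_to_tss
                for a in annotations
            ],
            "alternates": [",".join(a.alternates) for a in annotations],
        }
    )
    out = os.path.join(cfg.outdir, "annotation.tsv")
    _write_table(annot_df, out, cfg)
    outputs["annotation"] = out

    (genome_path,) = _require(cfg, "distribution", "genome")
    genome = read_genome_lengths(genome_path)
    dist = stage("distribution")(
        lambda: feature_distribution(consensus.regions, genes, genome)
    )
    dist_df = pd.DataFrame(
        {
            "feature": dist.classes,
            "observed_fraction": dist.observed_fraction,
            "background_fraction": dist.background_fraction,
        }
    )
    out = os.path.join(cfg.outdir, "distribution.tsv")
    _write_table(dist_df, out, cfg)
    outputs["distribution"] = out

    (tags_path,) = _require(cfg, "density", "tags")
    tags = read_tags(tags_path)
    dm = stage("density")(
        lambda: density_matrix(
            tags, consensus.regions, int(p["flank"]), int(p["bin_size"])
        )
    )
    frame = dm.to_frame().loc[order_rows_by_signal(dm)]
    out = os.path.join(cfg.outdir, "density_matrix.tsv")
    _write_table(frame, out, cfg, index=True, index_label="peak_id")
    outputs["density_matrix"] = out
    profile = pd.DataFrame(
        {"bin": frame.columns, "mean_tags": mean_profile(dm)}
    )
    out = os.path.join(cfg.outdir, "density_profile.tsv")
    _write_table(profile, out, cfg)
    outputs["density_profile"] = out
    return outputs


def run_expression_workflow(cfg: RunConfig) -> dict[str, str]:
    """Normalise -> correlate -> cluster -> group stats -> boxplots.

    Inputs: ``counts`` (probe CSV) and ``meta`` (sample metadata CSV).
    Config keys used from params: correlation_threshold.  The anchor gene
    and group labels come from inputs: ``anchor`` (default FOXM1),
    ``group_column`` (default 'group'), ``normal_label``/``tumour_label``.
    Constant (zero-variance) genes are excluded from correlation,
    clustering and z-scoring with a logged warning rather than aborting.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    p = cfg.params
    outputs: dict[str, str] = {}
    counts_path, meta_path = _require(cfg, "normalise", "counts", "meta")
    anchor = cfg.inputs.get("anchor", "FOXM1")
    group_col = cfg.inputs.get("group_column", "group")
    normal_label = cfg.inputs.get("normal_label", "normal")
    tumour_label = cfg.inputs.get("tumour_label", "OAC")

    cm = read_counts(counts_path, meta_path)
    try:
        norm = normalise(cm)
    except Exception as exc:
        raise RuntimeError(f"stage normalise: {exc}") from exc
    out = os.path.join(cfg.outdir, "normalised.csv")
    write_counts(norm, out, header_lines=cfg.provenance())
    outputs["normalised"] = out
    factors = pd.DataFrame(
        {
            "sample_id": norm.counts.columns,
            "pc_factor": norm.pc_factor.values,
            "ref_factor": norm.ref_factor.values,
        }
    )
    out = os.path.join(cfg.outdir, "factors.tsv")
    _write_table(factors, out, cfg)
    outputs["factors"] = out

    expr, constant = drop_constant_genes(norm.endogenous)
    if constant:
        log.warning("skipping constant genes: %s", constant)

    # correlation ranking operates on the log2 scale, the convention for
    # expression co-expression analysis (raw-count Pearson is skew-attenuated)
    try:
        results, sample_order = anchor_correlation(
            log2_counts(expr), anchor, p["correlation_threshold"]
        )
    except Exception as exc:
        raise RuntimeError(f"stage correlate: {exc}") from exc
    corr_df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "r": [r.r for r in results],
            "passes_threshold": [r.passes_threshold for r in results],
        }
    ).sort_values("r", ascending=False, kind="stable")
    out = os.path.join(cfg.outdir, "correlation.tsv")
    _write_table(corr_df, out, cfg)
    outputs["correlation"] = out

    try:
        z = zscore_by_gene(expr)
        _, gene_order = hierarchical_cluster(z, axis="genes")
        _, order_samples = hierarchical_cluster(z, axis="samples")
    except Exception as exc:
        raise RuntimeError(f"stage cluster: {exc}") from exc
    out = os.path.join(cfg.outdir, "cluster_gene_order.tsv")
    _write_table(pd.DataFrame({"gene_id": gene_order}), out, cfg)
    outputs["cluster_gene_order"] = out
    out = os.path.join(cfg.outdir, "cluster_sample_order.tsv")
    _write_table(pd.DataFrame({"sample_id": order_samples}), out, cfg)
    outputs["cluster_sample_order"] = out

    try:
        comparisons = group_statistics(
            expr, norm.sample_meta, group_col, normal_label, tumour_label
        )
    except Exception as exc:
        raise RuntimeError(f"stage groupstats: {exc}") from exc
    stats_df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in comparisons],
            "group_a": [c.group_a_label for c in comparisons],
            "group_b": [c.group_b_label for c in comparisons],
            "U": [c.statistic for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "fold_change": [c.fold_change for c in comparisons],
            "mark": [c.significance_mark for c in comparisons],
        }
    )
    out = os.path.join(cfg.outdir, "groupstats.tsv")
    _write_table(stats_df, out, cfg)
    outputs["groupstats"] = out

    normal_ids = norm.sample_meta.index[
        norm.sample_meta[group_col] == normal_label
    ].tolist()
    try:
        folds = fold_to_normal_median(expr, normal_ids)
    except Exception as exc:
        raise RuntimeError(f"stage boxplots: {exc}") from exc
    box_rows = []
    for gene in folds.index:
        for label, ids in (
            (normal_label, normal_ids),
            (
                tumour_label,
                [s for s in folds.columns if s not in set(normal_ids)],
            ),
        ):
            values = folds.loc[gene, ids]
            if len(values) < 4:
                continue
            s = boxplot_summary(values, gene, label)
            box_rows.append(
                {
                    "gene_id": gene,
                    "group": label,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "iqr": s.iqr,
                    "outliers": ",".join(f"{v:g}" for v in s.outliers),
                }
            )
    out = os.path.join(cfg.outdir, "boxplots.tsv")
    _write_table(pd.DataFrame(box_rows), out, cfg)
    outputs["boxplots"] = out
    return outputs
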