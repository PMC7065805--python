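"""End-to-end orchestration: config, stage runners and file-in/file-out glue.

Every stage reads and writes plain TSV (plus GMT/FASTA/PFM inputs), so each
one is independently testable and rerunnable. A run is deterministic given
the config (one seed drives every stochastic stage), and every output
directory receives the config's semantic hash so results can be traced to
the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decompose, diffexpr, enrichment, preprocess, signatures, slopes
from .io import (
    GeneSet,
    read_count_matrix,
    read_fasta_promoters,
    read_gmt,
    read_jaspar_pfm,
)
from .simulate import SimulationConfig, generate_dataset, write_dataset

__all__ = ["PipelineConfig", "run_simulate", "run_all", "config_hash"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, baselines and thresholds for a full pipeline run."""

    # inputs
    counts: str = "counts.tsv"
    annotation: str = "annotation.tsv"
    signature_gmt: str = "signatures.gmt"
    annotation_gmt: str = "annotation_sets.gmt"
    promoters: str = "promoters.fasta"
    pfms: str = "motifs.pfm"
    outdir: str = "results"

    # baselines
    baseline_strain: str = "WT"
    baseline_environment: str = "YPD"

    # thresholds and choices
    de_cutoff: float = 0.05
    residual_threshold: float = 2.5
    enrichment_cutoff: float = 0.05
    pwm_fraction: float = 0.8
    pfm_pseudocount: float = 0.5
    min_group_genes: int = 5
    outlier_z: float = 2.5
    min_total_count: int | None = None
    estimator: str = "reference_plugin"
    sigma_mode: str = "global_sd"
    n_clusters: int = 7
    esr_focal_kinases: tuple[str, ...] = ("Tpk123-as", "Pbs2-as")

    # simulation (used by the simulate stage)
    simulation: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_cutoff", "residual_threshold", "enrichment_cutoff", "pwm_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.estimator not in ("reference_plugin", "joint_ols"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the semantic fields (stable across field order)."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_hash.txt").write_text(config_hash(config) + "\n")


def run_simulate(config: PipelineConfig) -> dict[str, str]:
    """Write a complete synthetic dataset bundle into the input paths' directory."""
    sim_config = config.simulation_config()
    dataset = generate_dataset(sim_config)
    base = Path(config.counts).parent
    paths = write_dataset(dataset, base)
    logger.info("simulated %d genes x %d samples into %s",
                dataset.counts.shape[0], dataset.counts.shape[1], base)
    return paths


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig) -> Path:
    """Execute preprocess -> diffexpr -> slopes -> decomposition ->
    enrichment -> signatures, writing TSVs under the output directory."""
    outdir = Path(config.outdir)
    _stamp(config, outdir)
    t0 = time.time()

    def _log(stage: str, message: str) -> None:
        logger.info("[%6.1fs] %s: %s", time.time() - t0, stage, message)

    stage = "load"
    try:
        for path_name in ("counts", "annotation", "signature_gmt", "promoters", "pfms"):
            p = Path(getattr(config, path_name))
            if not p.exists():
                raise FileNotFoundError(f"missing input {path_name}: {p}")
        counts, ann = read_count_matrix(config.counts, config.annotation)
        signature_sets = {gs.name: gs for gs in read_gmt(config.signature_gmt)}
        annotation_sets = (
            read_gmt(config.annotation_gmt) if Path(config.annotation_gmt).exists() else []
        )
        promoters = read_fasta_promoters(config.promoters)
        pwms = read_jaspar_pfm(config.pfms, pseudocount=config.pfm_pseudocount)
        _log(stage, f"{counts.shape[0]} genes x {counts.shape[1]} samples")

        stage = "preprocess"
        counts = preprocess.filter_low_expression(counts, config.min_total_count)
        factors = preprocess.size_factors(counts)
        expr = preprocess.normalize_log2(counts, factors)
        fc_global = preprocess.fold_changes(
            expr, ann, preprocess.GLOBAL_BASELINE,
            config.baseline_strain, config.baseline_environment,
        )
        fc_matched = preprocess.fold_changes(
            expr, ann, preprocess.MATCHED_BASELINE,
            config.baseline_strain, config.baseline_environment,
        )
        factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
        fc_global.values.to_csv(outdir / "fc_global.tsv", sep="\t")
        fc_matched.values.to_csv(outdir / "fc_matched.tsv", sep="\t")
        (outdir / "baselines.json").write_text(json.dumps({
            "global": fc_global.baseline, "matched": fc_matched.baseline,
            "strain": config.baseline_strain, "environment": config.baseline_environment,
        }, indent=2))
        _log(stage, f"{counts.shape[0]} genes kept")

        stage = "diffexpr"
        environments = [
            e for e in dict.fromkeys(ann["environment"]) if e != config.baseline_environment
        ]
        de_results = {}
        for env in environments:
            de = diffexpr.call_de(
                expr, ann, env, cutoff=config.de_cutoff,
                baseline_environment=config.baseline_environment,
                baseline_strain=config.baseline_strain,
            )
            de_results[env] = de
            de.table.to_csv(outdir / f"de_{env}.tsv", sep="\t", index_label="gene")
        _log(stage, f"{sum(d.table['is_de'].sum() for d in de_results.values())} DE calls")

        stage = "slopes"
        testable = {e: d for e, d in de_results.items() if d.table["is_de"].sum() >= 10}
        slope_fits = slopes.fit_all_slopes(
            testable, fc_matched, ann,
            outlier_z=config.outlier_z, baseline_strain=config.baseline_strain,
        )
        pd.DataFrame([dataclasses.asdict(f) for f in slope_fits]).to_csv(
            outdir / "slopes.tsv", sep="\t", index=False
        )
        slopes.slope_matrix(slope_fits).to_csv(outdir / "slope_matrix.tsv", sep="\t")
        _log(stage, f"{len(slope_fits)} cells")

        stage = "decompose"
        fit = decompose.fit_additive(fc_global, ann, estimator=config.estimator)
        z, sigma, _ = decompose.residual_zscores(fit, sigma_mode=config.sigma_mode)
        calls, cell_z, sigma_cell = decompose.call_interactions(
            fit, threshold=config.residual_threshold, sigma_mode=config.sigma_mode
        )
        fit.env_effects.to_csv(outdir / "env_effects.tsv", sep="\t", index_label="gene")
        fit.kinase_effects.to_csv(outdir / "kinase_effects.tsv", sep="\t", index_label="gene")
        fit.r2.to_frame().to_csv(outdir / "r2.tsv", sep="\t", index_label="gene")
        z.to_csv(outdir / "residual_z.tsv", sep="\t", index_label="gene")
        pd.DataFrame(
            [(c.gene, c.kinase, c.environment, c.residual_z) for c in calls],
            columns=["gene", "kinase", "environment", "residual_z"],
        ).to_csv(outdir / "interaction_calls.tsv", sep="\t", index=False)
        summary = decompose.r2_distribution(fit, min_genes=min(100, fit.r2.notna().sum()))
        (outdir / "decomposition_summary.json").write_text(json.dumps({
            "mean_r2": summary.mean, "sigma": sigma, "sigma_cell": sigma_cell,
            "n_calls": len(calls), "estimator": config.estimator,
        }, indent=2))
        _log(stage, f"mean R^2 {summary.mean:.3f}, {len(calls)} interaction calls")

        stage = "enrich"
        universe = GeneSet("universe", "all analyzed genes", frozenset(counts.index))
        groups = decompose.group_calls(calls)
        geneset_rows = []
        for (kinase, env), genes in groups.items():
            if len(genes) < config.min_group_genes or not annotation_sets:
                continue
            for res in enrichment.hypergeometric_enrichment(
                genes, annotation_sets, universe, query_name=f"{kinase}@{env}"
            ):
                geneset_rows.append(dataclasses.asdict(res))
        pd.DataFrame(geneset_rows).to_csv(outdir / "geneset_enrichment.tsv", sep="\t", index=False)
        motif_results = enrichment.motif_enrichment(
            groups, promoters, pwms, universe,
            score_threshold_fraction=config.pwm_fraction,
            min_genes=config.min_group_genes,
        )
        pd.DataFrame([dataclasses.asdict(r) for r in motif_results]).to_csv(
            outdir / "motif_enrichment.tsv", sep="\t", index=False
        )
        edges, _by_env = enrichment.build_kinase_tf_network(
            motif_results, cutoff=config.enrichment_cutoff
        )
        pd.DataFrame([dataclasses.asdict(e) for e in edges]).to_csv(
            outdir / "network_edges.tsv", sep="\t", index=False
        )
        _log(stage, f"{len(edges)} kinase-TF edges")

        stage = "signatures"
        focal = [
            k for k in config.esr_focal_kinases if (ann["kinase"] == k).any()
        ]
        if "iESR" in signature_sets and "rESR" in signature_sets and focal:
            dists = signatures.esr_distributions(
                fc_matched, ann, signature_sets["iESR"], signature_sets["rESR"],
                focal, baseline_strain=config.baseline_strain,
            )
            pd.DataFrame(
                [
                    (d.group, d.set_name, d.median, d.iqr, d.rank_sum_p, len(d.values))
                    for d in dists
                ],
                columns=["group", "set", "median", "iqr", "rank_sum_p", "n_values"],
            ).to_csv(outdir / "esr_distributions.tsv", sep="\t", index=False)
        assignment, order = signatures.cluster_genes(
            fc_global, n_clusters=min(config.n_clusters, fc_global.values.shape[0])
        )
        assignment.to_frame().assign(
            heatmap_order=pd.Series(
                {g: i for i, g in enumerate(order)}, name="heatmap_order"
            )
        ).to_csv(outdir / "gene_clusters.tsv", sep="\t", index_label="gene")
        _log(stage, "done")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return outdir
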