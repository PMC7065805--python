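"""Gene-set-level views of the perturbation data.

Four operations:

* :func:`esr_distributions` - the distribution of matched-baseline fold
  changes of the induced (iESR) and repressed (rESR) stress-module genes
  for focal kinases versus the pooled remainder, with rank-sum location
  tests. A master regulator of the stress response shifts the induced
  module up and the repressed module down when inhibited; an upstream
  antagonist shows the mirror image.
* :func:`geneset_response_test` - per kinase, a two-factor (strain x gene)
  analysis of a dedicated gene set's fold changes against wild type in one
  environment, BH-adjusted across kinases, with the direction of the shift.
* :func:`geneset_residual_scatter` - measured vs additive-model-predicted
  set means per sample, with a set-level z that aggregates per-gene
  residuals as mean * sqrt(set size) / sigma (averaging tightens the null).
* :func:`cluster_genes` - hierarchical clustering of fold-change rows
  (1 - Pearson distance, average linkage) cut at a requested number of
  clusters, with a deterministic heatmap ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.formula.api import ols as _ols_formula
from statsmodels.stats.anova import anova_lm

from .decompose import AdditiveFit
from .diffexpr import benjamini_hochberg
from .io import GeneSet
from .preprocess import FoldChangeMatrix, MATCHED_BASELINE

__all__ = [
    "SignatureDistribution",
    "esr_distributions",
    "geneset_response_test",
    "geneset_residual_scatter",
    "cluster_genes",
]


@dataclass
class SignatureDistribution:
    group: str          # one kinase, or the pooled remainder label
    set_name: str
    values: np.ndarray  # per-(gene, sample) log2 fold changes
    median: float
    iqr: float
    rank_sum_p: float = np.nan   # focal group vs pooled remainder
    skipped: bool = False        # too few values to test


def _distribution(group: str, set_name: str, values: np.ndarray) -> SignatureDistribution:
    q1, q3 = (np.percentile(values, [25, 75]) if values.size else (np.nan, np.nan))
    return SignatureDistribution(
        group=group, set_name=set_name, values=values,
        median=float(np.median(values)) if values.size else np.nan,
        iqr=float(q3 - q1) if values.size else np.nan,
    )


def esr_distributions(
    fc_matched: FoldChangeMatrix,
    ann: pd.DataFrame,
    iesr: GeneSet,
    resr: GeneSet,
    focal_kinases: list[str],
    baseline_strain: str = "WT",
    remainder_label: str = "all-others",
) -> list[SignatureDistribution]:
    """Fold-change distributions of the two stress modules per focal kinase
    and for the pooled remaining mutants, across all environments, with a
    two-sided rank-sum test of each focal kinase against the remainder."""
    if fc_matched.baseline != MATCHED_BASELINE:
        raise ValueError("esr_distributions requires matched-environment fold changes")
    ann = ann.loc[fc_matched.samples]
    mutants = [k for k in dict.fromkeys(ann["kinase"]) if k != baseline_strain]
    for focal in focal_kinases:
        if focal not in mutants:
            raise ValueError(f"focal kinase {focal!r} has no samples")
    remainder = [k for k in mutants if k not in focal_kinases]
    out: list[SignatureDistribution] = []
    for gene_set in (iesr, resr):
        genes = [g for g in fc_matched.genes if g in gene_set]
        if not genes:
            raise ValueError(f"no genes of set {gene_set.name!r} in the matrix")
        sub = fc_matched.values.loc[genes]

        def _values(kinases: list[str]) -> np.ndarray:
            cols = ann.index[ann["kinase"].isin(kinases)]
            vals = sub[cols].to_numpy().ravel()
            return vals[np.isfinite(vals)]

        ref = _values(remainder)
        ref_dist = _distribution(remainder_label, gene_set.name, ref)
        for focal in focal_kinases:
            vals = _values([focal])
            dist = _distribution(focal, gene_set.name, vals)
            if vals.size < 2 or ref.size < 2:
                dist.skipped = True
            else:
                dist.rank_sum_p = float(
                    stats.mannwhitneyu(vals, ref, alternative="two-sided").pvalue
                )
            out.append(dist)
        out.append(ref_dist)
    return out


def geneset_response_test(
    fc_matched: FoldChangeMatrix,
    ann: pd.DataFrame,
    gene_set: GeneSet,
    environment: str,
    baseline_strain: str = "WT",
    min_set_genes: int = 3,
) -> pd.DataFrame:
    """Per-kinase two-factor (strain x gene) test of a gene set's response
    in one environment against wild type.

    For each mutant with samples in the environment, the set genes' fold
    changes (mutant samples + wild-type samples) are modeled as
    ``value ~ C(strain) + C(gene)``; the strain factor's p-value, the mean
    shift (direction: negative = attenuation of the set), and BH adjustment
    across kinases are reported.
    """
    if fc_matched.baseline != MATCHED_BASELINE:
        raise ValueError("geneset_response_test requires matched-environment fold changes")
    genes = [g for g in fc_matched.genes if g in gene_set]
    if len(genes) < min_set_genes:
        raise ValueError(
            f"set {gene_set.name!r} has {len(genes)} genes in the matrix; "
            f"need >= {min_set_genes}"
        )
    ann = ann.loc[fc_matched.samples]
    env_ann = ann[ann["environment"] == environment]
    wt_cols = env_ann.index[env_ann["kinase"] == baseline_strain]
    if len(wt_cols) == 0:
        raise ValueError(f"no {baseline_strain} samples in {environment!r}")
    sub = fc_matched.values.loc[genes]
    rows = []
    kinases = [k for k in dict.fromkeys(env_ann["kinase"]) if k != baseline_strain]
    for kinase in kinases:
        mut_cols = env_ann.index[env_ann["kinase"] == kinase]
        cols = list(wt_cols) + list(mut_cols)
        long = (
            sub[cols]
            .stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_1": "sample", "gene": "gene_id"})
        )
        long.columns = ["gene_id", "sample", "value"]
        long["strain"] = np.where(long["sample"].isin(mut_cols), kinase, baseline_strain)
        model = _ols_formula("value ~ C(strain) + C(gene_id)", data=long).fit()
        table = anova_lm(model, typ=2)
        pval = float(table.loc["C(strain)", "PR(>F)"])
        shift = float(
            sub[mut_cols].to_numpy().mean() - sub[list(wt_cols)].to_numpy().mean()
        )
        rows.append((kinase, shift, pval))
    result = pd.DataFrame(rows, columns=["kinase", "mean_shift", "pvalue"]).set_index("kinase")
    result["padj"] = benjamini_hochberg(result["pvalue"].to_numpy())
    result["direction"] = np.where(result["mean_shift"] < 0, "attenuation", "enhancement")
    return result


def geneset_residual_scatter(
    fit: AdditiveFit,
    gene_set: GeneSet,
    sigma: float | None = None,
    threshold: float = 2.5,
) -> pd.DataFrame:
    """Measured vs predicted set means per sample, with set-level z-scores.

    The per-sample set-level z is ``mean residual * sqrt(m) / sigma`` for a
    set of m genes, standard normal when the m per-gene residuals are
    independent null draws at scale sigma; a single-gene set reduces to that
    gene's per-sample residual z. ``sigma`` defaults to the pooled global
    residual standard deviation.
    """
    genes = [g for g in fit.genes if g in gene_set]
    if not genes:
        raise ValueError(f"no genes of set {gene_set.name!r} covered by the fit")
    if sigma is None:
        pooled = fit.residuals.to_numpy().ravel()
        pooled = pooled[np.isfinite(pooled)]
        sigma = float(pooled.std())
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m = len(genes)
    mean_fitted = fit.fitted.loc[genes].mean(axis=0)
    mean_resid = fit.residuals.loc[genes].mean(axis=0)
    z = mean_resid * np.sqrt(m) / sigma
    out = pd.DataFrame(
        {
            "mean_predicted": mean_fitted,
            "mean_measured": mean_fitted + mean_resid,
            "set_z": z,
            "flagged": np.abs(z) > threshold,
        }
    )
    out.index.name = "sample_id"
    return out


def cluster_genes(
    fc: FoldChangeMatrix | pd.DataFrame,
    n_clusters: int,
    subset: GeneSet | None = None,
) -> tuple[pd.Series, list[str]]:
    """Agglomerative clustering of genes (1 - Pearson correlation distance,
    average linkage) cut at ``n_clusters``; returns the gene -> cluster map
    and the dendrogram leaf order for heatmap display. Deterministic given
    the input row order."""
    values = fc.values if isinstance(fc, FoldChangeMatrix) else fc
    if subset is not None:
        values = values.loc[[g for g in values.index if g in subset]]
    n_genes = values.shape[0]
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > n_genes:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n_genes} genes")
    data = values.to_numpy(dtype=float)
    dist = pdist(data, metric="correlation")
    # constant rows have undefined correlation; treat them as maximally distant
    dist = np.nan_to_num(dist, nan=1.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    order = hierarchy.leaves_list(linkage)
    assignment = pd.Series(labels, index=values.index, name="cluster")
    ordered_genes = [values.index[i] for i in order]
    return assignment, ordered_genes
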