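"""Per-environment differentially expressed gene sets from wild-type replicates.

Each stress environment is compared with the rich-media baseline using the
wild-type replicates only: a per-gene Welch t-test on the log2 expression
scale, Benjamini-Hochberg adjustment across genes, and a declared adjusted
p-value cutoff (default 0.05). This is a deliberately simple, fully
in-repo replacement for a count-model Wald test; with four replicates per
side on an approximately variance-stabilized scale it is a standard
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet

__all__ = ["DEResult", "benjamini_hochberg", "call_de"]


@dataclass
class DEResult:
    """Differential-expression call for one environment vs the baseline."""

    environment: str
    baseline_environment: str
    table: pd.DataFrame  # log2fc, stat, pvalue, padj, is_de per gene
    cutoff: float

    @property
    def de_genes(self) -> GeneSet:
        members = frozenset(self.table.index[self.table["is_de"]])
        if not members:
            # an empty call set is legitimate; represent it without breaking
            # the non-empty GeneSet invariant by raising at access time
            raise ValueError(f"no differentially expressed genes in {self.environment!r}")
        return GeneSet(
            name=f"DE_{self.environment}",
            description=f"adjusted p < {self.cutoff} vs {self.baseline_environment}",
            members=members,
        )

    def de_gene_ids(self) -> list[str]:
        return self.table.index[self.table["is_de"]].tolist()


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment (monotone, capped at 1), order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    environment: str,
    cutoff: float = 0.05,
    baseline_environment: str = "YPD",
    baseline_strain: str = "WT",
) -> DEResult:
    """Welch t-test per gene: wild-type replicates in ``environment`` vs the
    baseline environment, BH-adjusted across genes.

    Genes with zero variance in both groups get p = 1 (conservative 0/0
    convention).
    """
    ann = ann.loc[expr.columns]
    env_cols = ann.index[(ann["kinase"] == baseline_strain) & (ann["environment"] == environment)]
    base_cols = ann.index[
        (ann["kinase"] == baseline_strain) & (ann["environment"] == baseline_environment)
    ]
    if len(env_cols) < 2 or len(base_cols) < 2:
        raise ValueError(
            f"need >= 2 {baseline_strain} replicates in both {environment!r} "
            f"({len(env_cols)}) and {baseline_environment!r} ({len(base_cols)})"
        )
    a = expr[env_cols].to_numpy()
    b = expr[base_cols].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, pval = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(pval)
    stat = np.where(degenerate, 0.0, stat)
    pval = np.where(degenerate, 1.0, pval)
    padj = benjamini_hochberg(pval)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "is_de": padj < cutoff,
        },
        index=expr.index,
    )
    return DEResult(
        environment=environment,
        baseline_environment=baseline_environment,
        table=table,
        cutoff=cutoff,
    )
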