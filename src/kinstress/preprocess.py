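"""Count normalization and the two fold-change matrices every figure uses.

Counts are depth-normalized with median-of-ratios size factors and placed on
a log2 scale with a pseudocount (a declared stand-in for a variance
stabilizing transform: the downstream analysis only needs an approximately
variance-stabilized log scale). Fold changes are taken against one of two
baselines:

* ``global_wt_ypd`` - wild type in rich media, the reference for the
  additive decomposition;
* ``matched_environment_wt`` - the wild-type average in the same
  environment, the reference for per-environment mutant responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeMatrix",
    "size_factors",
    "normalize_log2",
    "fold_changes",
    "filter_low_expression",
    "GLOBAL_BASELINE",
    "MATCHED_BASELINE",
]

GLOBAL_BASELINE = "global_wt_ypd"
MATCHED_BASELINE = "matched_environment_wt"


@dataclass
class FoldChangeMatrix:
    """Per-gene log2 fold changes with the declared reference recorded."""

    values: pd.DataFrame
    baseline: str
    baseline_strain: str
    baseline_environment: str

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample contribute: for
    those rows the per-sample ratio to the row geometric mean is taken, and
    the factor is the median ratio (midpoint convention on ties, as in
    ``numpy.median``).
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "filter low-expression genes before computing size factors"
        )
    logs = np.log(values[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_ratios = logs - log_geomean
    factors = np.exp(np.median(log_ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), the pipeline's expression scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        missing = factors.index[factors.isna()].tolist()
        raise ValueError(f"size factors missing for samples: {missing}")
    return np.log2(counts.div(factors, axis=1) + pseudocount)


def _wt_columns(ann: pd.DataFrame, strain: str, environment: str | None = None) -> pd.Index:
    mask = ann["kinase"] == strain
    if environment is not None:
        mask &= ann["environment"] == environment
    return ann.index[mask]


def fold_changes(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    baseline: str = GLOBAL_BASELINE,
    baseline_strain: str = "WT",
    baseline_environment: str = "YPD",
) -> FoldChangeMatrix:
    """Subtract the appropriate wild-type reference mean from every column.

    With the global baseline every sample is referenced to the wild-type
    mean in the baseline environment; with the matched baseline each sample
    is referenced to the wild-type mean in its own environment.
    """
    ann = ann.loc[expr.columns]
    if baseline == GLOBAL_BASELINE:
        ref_cols = _wt_columns(ann, baseline_strain, baseline_environment)
        if len(ref_cols) == 0:
            raise ValueError(
                f"no {baseline_strain} samples in {baseline_environment} for global baseline"
            )
        fc = expr.sub(expr[ref_cols].mean(axis=1), axis=0)
    elif baseline == MATCHED_BASELINE:
        fc = expr.copy()
        for env, env_ann in ann.groupby("environment", sort=False):
            ref_cols = _wt_columns(env_ann, baseline_strain)
            if len(ref_cols) == 0:
                raise ValueError(
                    f"environment {env!r} has no {baseline_strain} samples "
                    "for the matched baseline"
                )
            cols = env_ann.index
            fc[cols] = expr[cols].sub(expr[ref_cols].mean(axis=1), axis=0)
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return FoldChangeMatrix(
        values=fc,
        baseline=baseline,
        baseline_strain=baseline_strain,
        baseline_environment=baseline_environment,
    )


def filter_low_expression(counts: pd.DataFrame, min_total: int | None = None) -> pd.DataFrame:
    """Drop genes whose total count is below ``min_total`` (default: the
    number of samples, i.e. mean count >= 1). Row order is preserved."""
    if min_total is None:
        min_total = counts.shape[1]
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    kept = counts.loc[counts.sum(axis=1) >= min_total]
    if kept.empty:
        raise ValueError(f"no gene reaches total count {min_total}; nothing left to analyze")
    return kept
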