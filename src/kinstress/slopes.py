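"""Slope regression: does a kinase inhibition attenuate, amplify or
dysregulate the wild-type environmental response?

For each (kinase, environment) cell, the mutant's fold change relative to
wild type in the same environment is regressed (unweighted OLS with
intercept) on the wild-type response for the environment's differentially
expressed genes. A mutant that mounts the wild-type response gives slope 0;
a mutant whose environmental response is uniformly scaled by alpha gives
slope alpha - 1 (attenuation alpha < 1 -> negative slope, amplification
alpha > 1 -> positive). A flat slope with many outliers flags
dysregulation rather than scaling; outliers are counted at
|internally studentized residual| > 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diffexpr import DEResult
from .io import GeneSet
from .preprocess import FoldChangeMatrix, MATCHED_BASELINE

__all__ = ["SlopeFit", "fit_slope", "slope_matrix", "fit_all_slopes"]


@dataclass
class SlopeFit:
    kinase: str
    environment: str
    slope: float
    intercept: float
    n_genes: int
    r: float
    n_outliers: int
    status: str = "ok"  # or "missing_sample"

    @classmethod
    def missing(cls, kinase: str, environment: str) -> "SlopeFit":
        return cls(
            kinase=kinase, environment=environment,
            slope=np.nan, intercept=np.nan, n_genes=0, r=np.nan,
            n_outliers=0, status="missing_sample",
        )


def fit_slope(
    de_genes: GeneSet | Iterable[str],
    wt_fc: pd.Series,
    mut_fc: pd.Series,
    kinase: str = "",
    environment: str = "",
    outlier_z: float = 2.5,
    min_genes: int = 10,
) -> SlopeFit:
    """OLS of mutant-vs-WT fold change on the WT environmental response over
    the DE genes present in both vectors."""
    members = de_genes.members if isinstance(de_genes, GeneSet) else frozenset(de_genes)
    genes = [g for g in wt_fc.index if g in members and g in mut_fc.index]
    x = wt_fc.loc[genes].astype(float)
    y = mut_fc.loc[genes].astype(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_genes:
        raise ValueError(
            f"only {len(x)} usable DE genes for ({kinase!r}, {environment!r}); "
            f"need >= {min_genes}"
        )
    model = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    intercept, slope = model.params
    if np.allclose(model.resid, 0.0):
        studentized = np.zeros(len(x))  # perfect fit: no outliers by definition
    else:
        studentized = model.get_influence().resid_studentized_internal
    r = float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 and y.std() > 0 else np.nan
    return SlopeFit(
        kinase=kinase,
        environment=environment,
        slope=float(slope),
        intercept=float(intercept),
        n_genes=int(len(x)),
        r=r,
        n_outliers=int(np.sum(np.abs(studentized) > outlier_z)),
    )


def slope_matrix(fits: Sequence[SlopeFit]) -> pd.DataFrame:
    """Kinase x environment table of slopes; missing cells stay NaN."""
    kinases = list(dict.fromkeys(f.kinase for f in fits))
    envs = list(dict.fromkeys(f.environment for f in fits))
    table = pd.DataFrame(np.nan, index=pd.Index(kinases, name="kinase"),
                         columns=pd.Index(envs, name="environment"))
    for f in fits:
        if f.status == "ok":
            table.loc[f.kinase, f.environment] = f.slope
    return table


def fit_all_slopes(
    de_results: dict[str, DEResult],
    fc_matched: FoldChangeMatrix,
    ann: pd.DataFrame,
    outlier_z: float = 2.5,
    min_genes: int = 10,
    baseline_strain: str = "WT",
) -> list[SlopeFit]:
    """One fit per (kinase, environment) cell with a DE set; absent cells are
    reported with status ``missing_sample``.

    The x-vector is the wild-type log2 response (the DE table's fold change
    vs the baseline environment); the y-vector is the mutant's fold change
    against the matched-environment wild-type mean.
    """
    if fc_matched.baseline != MATCHED_BASELINE:
        raise ValueError("fit_all_slopes requires matched-environment fold changes")
    ann = ann.loc[fc_matched.samples]
    kinases = [k for k in dict.fromkeys(ann["kinase"]) if k != baseline_strain]
    fits: list[SlopeFit] = []
    for env, de in de_results.items():
        wt_fc = de.table["log2fc"]
        de_ids = frozenset(de.de_gene_ids())
        for kinase in kinases:
            cols = ann.index[(ann["kinase"] == kinase) & (ann["environment"] == env)]
            if len(cols) == 0:
                fits.append(SlopeFit.missing(kinase, env))
                continue
            mut_fc = fc_matched.values[cols].mean(axis=1)
            fits.append(
                fit_slope(
                    de_ids, wt_fc, mut_fc,
                    kinase=kinase, environment=env,
                    outlier_z=outlier_z, min_genes=min_genes,
                )
            )
    return fits
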