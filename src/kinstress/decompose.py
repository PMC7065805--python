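"""Additive decomposition of the perturbation x condition expression matrix.

The model: for each gene, the log2 fold change (vs wild type in the baseline
environment) of a sample from environment i with kinase j inhibited is

    delta_e = c_i + k_j

with the treatment-coding convention c[baseline env] = 0, k[WT] = 0. Two
estimators are offered:

* ``reference_plugin`` - the construction the study design suggests:
  c_i is the mean wild-type fold change in environment i, and k_j is the
  fold change of mutant j in the baseline environment. Each gene's
  parameters depend only on that gene's wild-type and baseline-media
  samples (local, no joint solve).
* ``joint_ols`` - the least-squares solution of the two-factor,
  no-interaction design over all samples, tolerant of missing cells.

On a complete, noise-free additive dataset the two coincide exactly.

Departures from additivity live in the residuals. Pooled residuals are
z-scored against one global scale; cells whose replicate-mean residual
exceeds the threshold (default 2.5 sigma, strict) are called candidate
kinase x environment interactions. Diagnostics cover the per-gene R^2
distribution, residual normality (QQ against a standard normal) and the
association between residual magnitude and expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .preprocess import FoldChangeMatrix, GLOBAL_BASELINE

__all__ = [
    "AdditiveFit",
    "ResidualCall",
    "fit_additive",
    "r2_distribution",
    "residual_zscores",
    "qq_normal",
    "residual_expression_association",
    "call_interactions",
    "group_calls",
]


@dataclass
class AdditiveFit:
    """Per-gene additive environment + kinase model over the whole dataset."""

    env_effects: pd.DataFrame     # genes x environments (baseline column 0)
    kinase_effects: pd.DataFrame  # genes x strains (WT column 0)
    fitted: pd.DataFrame          # genes x samples
    residuals: pd.DataFrame       # measured - fitted
    r2: pd.Series                 # per gene, squared Pearson corr(fitted, measured)
    ann: pd.DataFrame
    estimator: str
    baseline_strain: str
    baseline_environment: str

    @property
    def genes(self) -> pd.Index:
        return self.fitted.index


@dataclass(frozen=True)
class ResidualCall:
    gene: str
    kinase: str
    environment: str
    residual_z: float

    @property
    def sign(self) -> int:
        return 1 if self.residual_z > 0 else -1


def _r2_rows(measured: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """Row-wise squared Pearson correlation; NaN where either side is constant."""
    m = measured - measured.mean(axis=1, keepdims=True)
    f = fitted - fitted.mean(axis=1, keepdims=True)
    num = (m * f).sum(axis=1)
    den = np.sqrt((m ** 2).sum(axis=1) * (f ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r ** 2


def _check_connected(ann: pd.DataFrame, baseline_strain: str, baseline_environment: str) -> None:
    """The two-factor design is identifiable iff the kinase/environment
    incidence graph is connected."""
    strains = list(dict.fromkeys(ann["kinase"]))
    envs = list(dict.fromkeys(ann["environment"]))
    s_idx = {s: i for i, s in enumerate(strains)}
    e_idx = {e: len(strains) + i for i, e in enumerate(envs)}
    rows = [s_idx[s] for s in ann["kinase"]]
    cols = [e_idx[e] for e in ann["environment"]]
    n = len(strains) + len(envs)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph + graph.T, directed=False)
    if n_comp > 1:
        base_label = labels[s_idx.get(baseline_strain, 0)]
        disconnected = [name for name, i in {**s_idx, **e_idx}.items() if labels[i] != base_label]
        raise ValueError(
            f"design is disconnected; block not linked to the baseline: {disconnected}"
        )


def fit_additive(
    fc: FoldChangeMatrix,
    ann: pd.DataFrame,
    estimator: str = "reference_plugin",
) -> AdditiveFit:
    """Fit delta_e = c_i + k_j per gene on global-baseline fold changes."""
    if fc.baseline != GLOBAL_BASELINE:
        raise ValueError("fit_additive requires global-baseline fold changes")
    if estimator not in ("reference_plugin", "joint_ols"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ann = ann.loc[fc.samples]
    base_strain, base_env = fc.baseline_strain, fc.baseline_environment
    envs = list(dict.fromkeys(ann["environment"]))
    strains = list(dict.fromkeys(ann["kinase"]))
    if base_strain not in strains:
        raise ValueError(f"no {base_strain} samples in the dataset")
    values = fc.values

    if estimator == "reference_plugin":
        env_eff = pd.DataFrame(np.nan, index=values.index, columns=envs)
        for env in envs:
            cols = ann.index[(ann["kinase"] == base_strain) & (ann["environment"] == env)]
            if len(cols) == 0:
                raise ValueError(f"environment {env!r} has no {base_strain} replicates")
            env_eff[env] = values[cols].mean(axis=1)
        env_eff[base_env] = 0.0  # convention; WT@baseline fold changes are ~0 already
        kin_eff = pd.DataFrame(np.nan, index=values.index, columns=strains)
        kin_eff[base_strain] = 0.0
        for strain in strains:
            if strain == base_strain:
                continue
            cols = ann.index[(ann["kinase"] == strain) & (ann["environment"] == base_env)]
            if len(cols) == 0:
                continue  # flagged missing: stays NaN
            kin_eff[strain] = values[cols].mean(axis=1)
    else:
        _check_connected(ann, base_strain, base_env)
        free_envs = [e for e in envs if e != base_env]
        free_strains = [s for s in strains if s != base_strain]
        p = len(free_envs) + len(free_strains)
        X = np.zeros((len(ann), p))
        for j, env in enumerate(free_envs):
            X[(ann["environment"] == env).to_numpy(), j] = 1.0
        for j, strain in enumerate(free_strains):
            X[(ann["kinase"] == strain).to_numpy(), len(free_envs) + j] = 1.0
        beta, *_ = np.linalg.lstsq(X, values.to_numpy().T, rcond=None)
        env_eff = pd.DataFrame(0.0, index=values.index, columns=envs)
        env_eff[free_envs] = beta[: len(free_envs)].T
        kin_eff = pd.DataFrame(0.0, index=values.index, columns=strains)
        kin_eff[free_strains] = beta[len(free_envs):].T

    fitted_arr = (
        env_eff.reindex(columns=ann["environment"]).to_numpy()
        + kin_eff.fillna(0.0).reindex(columns=ann["kinase"]).to_numpy()
    )
    fitted = pd.DataFrame(fitted_arr, index=values.index, columns=values.columns)
    residuals = values - fitted
    r2 = pd.Series(
        _r2_rows(values.to_numpy(), fitted.to_numpy()), index=values.index, name="r2"
    )
    return AdditiveFit(
        env_effects=env_eff,
        kinase_effects=kin_eff,
        fitted=fitted,
        residuals=residuals,
        r2=r2,
        ann=ann,
        estimator=estimator,
        baseline_strain=base_strain,
        baseline_environment=base_env,
    )


@dataclass
class R2Summary:
    mean: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_genes: int


def r2_distribution(fit: AdditiveFit, bins: int = 20, min_genes: int = 100) -> R2Summary:
    """Pooled per-gene R^2: mean plus binned frequencies on [0, 1]."""
    r2 = fit.r2.dropna()
    if len(r2) < min_genes:
        raise ValueError(f"need >= {min_genes} genes with defined R^2, have {len(r2)}")
    counts, edges = np.histogram(r2, bins=bins, range=(0.0, 1.0))
    return R2Summary(mean=float(r2.mean()), bin_edges=edges, counts=counts, n_genes=len(r2))


def residual_zscores(
    fit: AdditiveFit,
    sigma_mode: str = "global_sd",
    min_pooled: int = 1000,
) -> tuple[pd.DataFrame, float, float]:
    """Z-score every residual against one global scale.

    The scale is estimated once from the pool of all residuals of all genes
    and samples: the standard deviation (``global_sd``) or 1.4826 * MAD
    (``global_mad``). Returns ``(z, sigma, pooled_mean)``.
    """
    pooled = fit.residuals.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < min_pooled:
        raise ValueError(f"need >= {min_pooled} pooled residuals, have {pooled.size}")
    mean = float(pooled.mean())
    if sigma_mode == "global_sd":
        sigma = float(pooled.std())
    elif sigma_mode == "global_mad":
        sigma = float(1.4826 * np.median(np.abs(pooled - np.median(pooled))))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if sigma == 0:
        raise ValueError("pooled residual scale is zero; z-scores undefined")
    return (fit.residuals - mean) / sigma, sigma, mean


def qq_normal(
    zscores, band: float = 0.25, min_points: int = 1000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical vs standard-normal quantiles at plotting positions
    (i - 0.5)/n; returns (theoretical, empirical, fraction within ``band``
    of the x = y line)."""
    z = np.asarray(zscores, dtype=float).ravel()
    z = z[np.isfinite(z)]
    if z.size < min_points:
        raise ValueError(f"need >= {min_points} z values, have {z.size}")
    if z.std() == 0:
        raise ValueError("constant input: QQ plot is degenerate")
    empirical = np.sort(z)
    theoretical = stats.norm.ppf((np.arange(1, z.size + 1) - 0.5) / z.size)
    within = float(np.mean(np.abs(empirical - theoretical) <= band))
    return theoretical, empirical, within


@dataclass
class ResidualExpressionAssociation:
    correlation: float
    density: pd.DataFrame  # binned 2D counts: |residual| rows x expression cols
    degenerate: bool = False


def residual_expression_association(
    fit: AdditiveFit, mean_expr: pd.Series, bins: int = 40
) -> ResidualExpressionAssociation:
    """Correlation between |residual| and mean expression level, plus a
    binned 2D density table (the contour-plot summary)."""
    mean_expr = mean_expr.reindex(fit.genes)
    abs_resid = np.abs(fit.residuals.to_numpy())
    expr_bcast = np.broadcast_to(mean_expr.to_numpy()[:, None], abs_resid.shape)
    x = expr_bcast.ravel()
    y = abs_resid.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        empty = pd.DataFrame()
        return ResidualExpressionAssociation(np.nan, empty, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    hist, xedges, yedges = np.histogram2d(x, y, bins=bins)
    density = pd.DataFrame(
        hist,
        index=pd.Index(xedges[:-1], name="mean_expression"),
        columns=pd.Index(yedges[:-1], name="abs_residual"),
    )
    return ResidualExpressionAssociation(r, density)


def _cell_residuals(fit: AdditiveFit) -> pd.DataFrame:
    """Replicate-mean residual per (gene, kinase, environment) cell; columns
    are a MultiIndex (kinase, environment)."""
    groups = fit.ann.groupby(["kinase", "environment"], sort=False).groups
    cells = {}
    for (kinase, env), samples in groups.items():
        cells[(kinase, env)] = fit.residuals[list(samples)].mean(axis=1)
    out = pd.DataFrame(cells)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["kinase", "environment"])
    return out


def call_interactions(
    fit: AdditiveFit,
    threshold: float = 2.5,
    sigma_mode: str = "global_sd",
) -> tuple[list[ResidualCall], pd.DataFrame, float]:
    """Call kinase x environment interactions from cell-level residuals.

    The unit of calling is the (gene, kinase, environment) cell: with
    replicates, the cell's residual is the replicate-mean residual. The null
    scale is estimated from the pool of mutant-in-stress cell residuals
    (cells with kinase != WT and environment != baseline) - under the
    plug-in estimator the remaining cells are structurally (near-)zero and
    would deflate the scale. Cells with |z| strictly greater than the
    threshold are returned, sorted by |z| descending (ties by gene id,
    kinase, environment); the wild-type-in-baseline cell is never eligible.

    Returns ``(calls, cell_z, sigma_cell)``.
    """
    cells = _cell_residuals(fit)
    kinases = cells.columns.get_level_values("kinase")
    envs = cells.columns.get_level_values("environment")
    informative = (kinases != fit.baseline_strain) & (envs != fit.baseline_environment)
    pool = cells.loc[:, informative].to_numpy().ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size < 2:
        raise ValueError("not enough mutant-in-stress cells to estimate the calling scale")
    mean = float(pool.mean())
    if sigma_mode == "global_sd":
        sigma = float(pool.std())
    elif sigma_mode == "global_mad":
        sigma = float(1.4826 * np.median(np.abs(pool - np.median(pool))))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if sigma == 0:
        raise ValueError("cell residual scale is zero")
    z = (cells - mean) / sigma
    eligible = ~((kinases == fit.baseline_strain) & (envs == fit.baseline_environment))
    z = z.loc[:, eligible]

    calls: list[ResidualCall] = []
    if np.isfinite(threshold):
        exceed = np.abs(z.to_numpy()) > threshold
        gi, ci = np.nonzero(exceed)
        cols = z.columns
        for g, c in zip(gi, ci):
            kinase, env = cols[c]
            calls.append(
                ResidualCall(
                    gene=str(z.index[g]), kinase=kinase, environment=env,
                    residual_z=float(z.iloc[g, c]),
                )
            )
        calls.sort(key=lambda call: (-abs(call.residual_z), call.gene, call.kinase,
                                     call.environment))
    return calls, z, sigma


def group_calls(calls: Sequence[ResidualCall]) -> dict[tuple[str, str], list[str]]:
    """Sorted gene lists per (kinase, environment) cell."""
    groups: dict[tuple[str, str], list[str]] = {}
    for call in calls:
        groups.setdefault((call.kinase, call.environment), []).append(call.gene)
    return {key: sorted(set(genes)) for key, genes in groups.items()}
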