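"""Annotation of residual call sets: gene-set enrichment, promoter motif
scanning, and the kinase -> transcription-factor network.

Gene-set (GO-style) enrichment is an upper-tail hypergeometric test of a
query gene list against each supplied set within a declared universe, with
Benjamini-Hochberg adjustment across sets. Motif enrichment replaces
de-novo discovery with known-motif scanning: each promoter is scored with a
PWM's log-odds against a background model on both strands, a gene is a
"hit" when its best window reaches a declared fraction of the PWM's maximum
achievable score, and hit genes are tested hypergeometrically within each
(kinase, environment) call group. Significant (kinase, TF) pairs become
edges of per-environment bipartite networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io import GeneSet, PWM

__all__ = [
    "EnrichmentResult",
    "KinaseTFEdge",
    "hypergeometric_enrichment",
    "scan_pwm",
    "motif_enrichment",
    "build_kinase_tf_network",
]

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_PENALTY = -1e9  # windows containing N can never be hits


@dataclass
class EnrichmentResult:
    query_name: str
    set_name: str
    overlap: int        # k
    query_size: int     # n
    set_size: int       # K
    universe_size: int  # N
    pvalue: float
    padj: float = np.nan
    kinase: str | None = None
    environment: str | None = None


@dataclass(frozen=True)
class KinaseTFEdge:
    kinase: str
    environment: str
    tf_name: str
    padj: float


def hypergeometric_enrichment(
    query: GeneSet | Sequence[str],
    sets: Sequence[GeneSet],
    universe: GeneSet,
    query_name: str | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p per set, BH-adjusted across sets.

    Query genes outside the universe are dropped with a warning; set members
    outside the universe do not count toward K.
    """
    uni = universe.members
    if not uni:
        raise ValueError("universe is empty")
    if isinstance(query, GeneSet):
        name = query_name or query.name
        q_raw = query.members
    else:
        name = query_name or "query"
        q_raw = frozenset(query)
    q = q_raw & uni
    if len(q) < len(q_raw):
        logger.warning(
            "%d query genes outside the universe dropped for %s", len(q_raw) - len(q), name
        )
    N, n = len(uni), len(q)
    results = []
    for gs in sets:
        K = len(gs.members & uni)
        k = len(gs.members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(
            EnrichmentResult(
                query_name=name, set_name=gs.name,
                overlap=k, query_size=n, set_size=K, universe_size=N,
                pvalue=min(p, 1.0),
            )
        )
    if results:
        padj = benjamini_hochberg([r.pvalue for r in results])
        for r, adj in zip(results, padj):
            r.padj = float(adj)
    return results


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _window_scores(encoded: np.ndarray, lodds5: np.ndarray) -> np.ndarray:
    """Scores of all windows of one strand; lodds5 is 5 x L (N row penalized)."""
    L = lodds5.shape[1]
    n_win = encoded.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lodds5[encoded[j:j + n_win], j]
    return scores


def scan_pwm(
    promoters: Mapping[str, str],
    pwm: PWM,
    score_threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Score every promoter window on both strands with the PWM's log-odds.

    A gene is a hit when its best window scores at least
    ``score_threshold_fraction`` of the PWM's maximum achievable log-odds
    (which must be positive: an uninformative PWM yields no hits).
    Promoters shorter than the motif are flagged and scored as non-hits.
    Returns a DataFrame indexed by gene with ``best_score``, ``hit`` and
    ``too_short`` columns.
    """
    if not promoters:
        raise ValueError("no promoters supplied")
    if not 0.0 < score_threshold_fraction <= 1.0:
        raise ValueError("score_threshold_fraction must be in (0, 1]")
    lodds = pwm.log_odds()
    lodds = np.where(np.isfinite(lodds), lodds, _N_PENALTY)
    lodds5 = np.vstack([lodds, np.full(pwm.length, _N_PENALTY)])
    # reverse complement: base b at motif position j pairs with 3-b at L-1-j
    lodds5_rc = np.vstack([lodds[::-1, ::-1], np.full(pwm.length, _N_PENALTY)])
    max_score = pwm.max_score()
    cutoff = score_threshold_fraction * max_score
    rows = []
    for gene, seq in promoters.items():
        if len(seq) < pwm.length:
            rows.append((gene, -np.inf, False, True))
            continue
        encoded = _encode(seq)
        best = -np.inf
        for mat in (lodds5, lodds5_rc):
            scores = _window_scores(encoded, mat)
            if scores.size:
                best = max(best, float(scores.max()))
        hit = bool(max_score > 0 and best >= cutoff)
        rows.append((gene, best, hit, False))
    return pd.DataFrame(
        rows, columns=["gene", "best_score", "hit", "too_short"]
    ).set_index("gene")


def motif_enrichment(
    call_groups: Mapping[tuple[str, str], Sequence[str]],
    promoters: Mapping[str, str],
    pwms: Sequence[PWM],
    universe: GeneSet,
    score_threshold_fraction: float = 0.8,
    min_genes: int = 5,
) -> list[EnrichmentResult]:
    """Per (kinase, environment) call group and PWM: hypergeometric
    enrichment of motif-hit genes, BH across PWMs within each group.

    Groups smaller than ``min_genes`` are skipped (logged). Group genes with
    no supplied promoter are a hard error naming the genes.
    """
    uni_genes = sorted(universe.members)
    missing_uni = [g for g in uni_genes if g not in promoters]
    if missing_uni:
        raise ValueError(f"universe genes with no promoter supplied: {missing_uni[:10]}")
    uni_promoters = {g: promoters[g] for g in uni_genes}
    hit_sets = {}
    for pwm in pwms:
        scan = scan_pwm(uni_promoters, pwm, score_threshold_fraction)
        hits = frozenset(scan.index[scan["hit"]])
        if hits:
            hit_sets[pwm.tf_name] = GeneSet(pwm.tf_name, "motif hit genes", hits)
        else:
            hit_sets[pwm.tf_name] = None
    results: list[EnrichmentResult] = []
    for (kinase, env), genes in call_groups.items():
        genes = sorted(set(genes))
        missing = [g for g in genes if g not in promoters]
        if missing:
            raise ValueError(
                f"call group ({kinase}, {env}) has genes with no promoter: {missing[:10]}"
            )
        if len(genes) < min_genes:
            logger.info(
                "skipping group (%s, %s): %d genes < %d", kinase, env, len(genes), min_genes
            )
            continue
        name = f"{kinase}@{env}"
        group_results = []
        for pwm in pwms:
            hs = hit_sets[pwm.tf_name]
            if hs is None:
                group_results.append(
                    EnrichmentResult(
                        query_name=name, set_name=pwm.tf_name,
                        overlap=0, query_size=len(set(genes) & universe.members),
                        set_size=0, universe_size=len(universe.members),
                        pvalue=1.0, kinase=kinase, environment=env,
                    )
                )
                continue
            res = hypergeometric_enrichment(genes, [hs], universe, query_name=name)[0]
            res.kinase, res.environment = kinase, env
            group_results.append(res)
        padj = benjamini_hochberg([r.pvalue for r in group_results])
        for r, adj in zip(group_results, padj):
            r.padj = float(adj)
        results.extend(group_results)
    return results


def build_kinase_tf_network(
    enrichments: Sequence[EnrichmentResult],
    cutoff: float = 0.05,
    pooled_label: str = "all-other-environments",
    highlight_environments: Sequence[str] = (),
) -> tuple[list[KinaseTFEdge], dict[str, list[KinaseTFEdge]]]:
    """Edges for adjusted p < cutoff, grouped per environment.

    ``highlight_environments`` get their own subgraphs; every other
    environment's edges are pooled under ``pooled_label`` (the
    complex-network-vs-rest presentation convention). With no highlights,
    each environment gets its own subgraph.
    """
    edges = [
        KinaseTFEdge(r.kinase, r.environment, r.set_name, float(r.padj))
        for r in enrichments
        if r.kinase is not None and np.isfinite(r.padj) and r.padj < cutoff
    ]
    by_env: dict[str, list[KinaseTFEdge]] = {}
    highlights = set(highlight_environments)
    for edge in edges:
        if not highlights or edge.environment in highlights:
            by_env.setdefault(edge.environment, []).append(edge)
        else:
            by_env.setdefault(pooled_label, []).append(edge)
    return edges, by_env
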