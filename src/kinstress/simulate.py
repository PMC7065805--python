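"""Synthetic perturbation-transcriptome generator with known ground truth.

The generator emulates a perturbation panel of analog-sensitive (AS) kinase
strains plus a wild type, profiled across a battery of environments: log2
expression of each gene is a baseline plus an additive environment effect,
an additive kinase-inhibition effect, sparse kinase-by-environment
interaction effects, and Gaussian log-scale noise; counts are then drawn
from a negative binomial with per-gene dispersion and per-sample library
size. Every downstream stage of the pipeline (normalization, fold changes,
differential expression, slope regression, additive decomposition, motif
and gene-set enrichment, stress-signature scoring) has its ground truth
recorded in :class:`SimulationTruth`.

Structured features planted by default:

* an induced and a repressed pan-stress module (iESR / rESR): members
  respond in *every* stress environment with a coherent sign;
* master regulator kinases with opposite coupling to the two modules
  (inhibiting the PKA-like master de-represses the induced module and
  represses the repressed module; the antagonist does the reverse);
* transcription-factor target sets whose promoters carry a planted binding
  motif, optionally wired to a specific (kinase, environment) cell so that
  inhibiting that kinase in that environment dysregulates exactly the TF's
  targets;
* optional per-(kinase, environment) response attenuation, expressed as
  interaction effects ``(alpha - 1) * env_effect`` so an attenuated mutant
  shows a scaled-down environmental response.

The ``dispersion == 0`` limit is deterministic (counts are the rounded
means), which is the noise-free oracle used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GeneSet,
    PWM,
    write_count_matrix,
    write_fasta_promoters,
    write_gmt,
    write_jaspar_pfm,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticDataset",
    "generate_truth",
    "simulate_counts",
    "generate_promoters",
    "generate_annotation_sets",
    "generate_motif_library",
    "generate_dataset",
    "write_dataset",
    "DEFAULT_KINASES",
    "DEFAULT_ENVIRONMENTS",
]

# 28 AS kinase strains; named members of the stress-signaling panel first,
# generic labels padding the remainder.
DEFAULT_KINASES: tuple[str, ...] = (
    "Tpk123-as", "Pbs2-as", "Hog1-as", "Ste11-as", "Sch9-as", "Ypk1-as",
    "Ypk3-as", "Ire1-as", "Cdc15-as", "Cdc5-as", "Cdc7-as", "Snf1-as",
    "Ctk1-as", "Fus3-as", "Kin1-as", "Ksp1-as", "Mrk1-as", "Rim11-as",
    "Rim15-as", "Ssn3-as", "Yak1-as", "Ygk3-as", "Kin2-as", "Kin3-as",
    "Kin4-as", "Kin5-as", "Kin6-as", "Kin7-as",
)

# Ten environments; the first is the rich-media baseline.
DEFAULT_ENVIRONMENTS: tuple[str, ...] = (
    "YPD", "SDC", "heat-shock", "NaCl", "glucose-depletion", "tunicamycin",
    "menadione", "AZC", "rapamycin", "fluconazole",
)

_MISSING_CELL_SEED = 1914  # fixed: which mutant cells are absent is arbitrary
_STREAMS = {"truth": 0, "counts": 1, "promoters": 2, "sets": 3, "motifs": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationConfig:
    """Parameters of the simulated study design and its noise model.

    Defaults reproduce the study layout: 28 mutant strains plus wild type,
    10 environments, 4 wild-type replicates per environment, a single
    replicate per mutant cell, and 19 missing mutant cells, giving
    28*10 - 19 + 4*10 = 301 samples. Effects are log2-scale.
    """

    n_genes: int = 6000
    kinases: tuple[str, ...] = DEFAULT_KINASES
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS
    baseline_environment: str = "YPD"
    baseline_strain: str = "WT"
    wt_replicates: int = 4
    mutant_replicates: int = 1
    missing_cells: tuple[tuple[str, str], ...] | None = None
    n_missing: int = 19

    # additive effect structure (log2)
    env_responsive_fraction: float = 0.3
    env_effect_mean: float = 2.0
    env_effect_sd: float = 0.5
    kinase_responsive_fraction: float = 0.25
    kinase_effect_mean: float = 2.0
    kinase_effect_sd: float = 0.5

    # interactions (the nonlinearity residual analysis must find)
    interaction_density: float = 0.005
    interaction_effect_size: float = 2.0

    # noise model
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 8.5
    baseline_log2_sd: float = 1.0
    dispersion_range: tuple[float, float] = (0.005, 0.05)
    library_size_range: tuple[float, float] = (0.7, 1.4)

    # stress-signature modules and their master kinases
    iesr_size: int = 150
    resr_size: int = 150
    esr_kinase_effect: float = 1.5
    master_kinases: tuple[tuple[str, int], ...] = (("Tpk123-as", 1), ("Pbs2-as", -1))
    regulon_size: int = 42
    regulon_environment: str = "heat-shock"

    # promoter / motif structure
    n_tfs: int = 6
    tf_targets_per_tf: int = 40
    motif_length: int = 10
    promoter_length: int = 500
    kinase_tf_links: tuple[tuple[str, str, str], ...] = (("Hog1-as", "NaCl", "TF1"),)

    # per-(kinase, environment) uniform response attenuation factors alpha
    attenuations: tuple[tuple[str, str, float], ...] = ()

    seed: int = 0

    def __post_init__(self) -> None:
        self.kinases = tuple(self.kinases)
        self.environments = tuple(self.environments)
        self.master_kinases = tuple((k, int(s)) for k, s in self.master_kinases)
        self.kinase_tf_links = tuple(tuple(x) for x in self.kinase_tf_links)
        self.attenuations = tuple((k, e, float(a)) for k, e, a in self.attenuations)
        if self.missing_cells is not None:
            self.missing_cells = tuple(tuple(c) for c in self.missing_cells)
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(set(self.kinases)) != len(self.kinases):
            raise ValueError("kinase labels must be unique")
        if self.baseline_strain in self.kinases:
            raise ValueError("baseline strain must not appear among mutant kinases")
        if self.baseline_environment not in self.environments:
            raise ValueError("baseline environment must be listed in environments")
        if not 0.0 <= self.interaction_density < 1.0:
            raise ValueError("interaction_density must be in [0, 1)")
        if self.wt_replicates < 1 or self.mutant_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        lo, hi = self.dispersion_range
        if lo < 0 or hi < lo:
            raise ValueError("dispersion_range must satisfy 0 <= lo <= hi")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must satisfy 0 < lo <= hi")
        known_tfs = {f"TF{i + 1}" for i in range(self.n_tfs)}
        for kinase, env, tf in self.kinase_tf_links:
            if kinase not in self.kinases or env not in self.environments:
                raise ValueError(f"kinase_tf_link references unknown cell ({kinase}, {env})")
            if env == self.baseline_environment:
                raise ValueError("kinase_tf_links must target a stress environment")
            if tf not in known_tfs:
                raise ValueError(f"kinase_tf_link references unknown TF {tf!r}")
        for kinase, env, alpha in self.attenuations:
            if kinase not in self.kinases or env not in self.environments:
                raise ValueError(f"attenuation references unknown cell ({kinase}, {env})")
            if alpha < 0:
                raise ValueError("attenuation alpha must be >= 0")

    @property
    def stress_environments(self) -> tuple[str, ...]:
        return tuple(e for e in self.environments if e != self.baseline_environment)

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def resolve_missing_cells(self) -> tuple[tuple[str, str], ...]:
        """The mutant (kinase, environment) cells absent from the design.

        When unspecified, a fixed-seed draw of ``n_missing`` stress cells is
        used, always containing the PKA-like master kinase under glucose
        depletion if those labels exist in the design. The default draw never
        removes more than 10% of the eligible mutant cells (pass
        ``missing_cells`` explicitly for exact control), so reduced designs
        keep most of their mutant-in-stress measurements.
        """
        if self.missing_cells is not None:
            return self.missing_cells
        forced: list[tuple[str, str]] = []
        if "Tpk123-as" in self.kinases and "glucose-depletion" in self.environments:
            forced.append(("Tpk123-as", "glucose-depletion"))
        eligible = [
            (k, e)
            for k in self.kinases
            for e in self.stress_environments
            if (k, e) not in forced
        ]
        cap = int(0.1 * len(eligible))
        n_extra = max(0, min(self.n_missing - len(forced), cap))
        rng = np.random.default_rng(_MISSING_CELL_SEED)
        idx = rng.choice(len(eligible), size=n_extra, replace=False)
        return tuple(forced + [eligible[i] for i in sorted(idx)])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth underlying one simulated dataset."""

    genes: list[str]
    env_effects: pd.DataFrame        # genes x environments, baseline column zero
    kinase_effects: pd.DataFrame     # genes x (WT + kinases), WT column zero
    interaction_effects: dict[tuple[str, str, str], float]  # (gene, kinase, env)
    baseline_log2: pd.Series
    dispersion: pd.Series
    iesr: GeneSet
    resr: GeneSet
    regulon: GeneSet
    tf_target_map: dict[str, GeneSet]
    master_kinase_sign: dict[str, int]

    def interaction_genes(self) -> frozenset[str]:
        return frozenset(g for g, _, _ in self.interaction_effects)


def _sparse_effects(
    rng: np.random.Generator,
    n_genes: int,
    fraction: float,
    mean: float,
    sd: float,
) -> np.ndarray:
    """Sparse bimodal effects: a responsive subset gets +/-N(mean, sd^2)."""
    responsive = rng.random(n_genes) < fraction
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    magnitudes = np.abs(rng.normal(mean, sd, size=n_genes))
    return np.where(responsive, signs * magnitudes, 0.0)


def generate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw the ground-truth effect structure for one simulated study."""
    rng = _rng(config.seed, "truth")
    genes = config.gene_names()
    n = config.n_genes
    envs = list(config.environments)
    strains = [config.baseline_strain] + list(config.kinases)

    # disjoint structured modules (sizes shrink gracefully on tiny gene sets)
    order = rng.permutation(n)
    n_iesr = min(config.iesr_size, max(1, n // 4))
    n_resr = min(config.resr_size, max(1, n // 4))
    iesr_idx = order[:n_iesr]
    resr_idx = order[n_iesr:n_iesr + n_resr]
    rest = order[n_iesr + n_resr:]
    n_reg = min(config.regulon_size, max(1, len(rest))) if len(rest) else 0
    regulon_idx = rest[:n_reg] if n_reg else order[:1]

    env_effects = pd.DataFrame(0.0, index=genes, columns=envs)
    for env in config.stress_environments:
        env_effects[env] = _sparse_effects(
            rng, n, config.env_responsive_fraction,
            config.env_effect_mean, config.env_effect_sd,
        )
        # pan-stress modules: coherent sign in every stress environment
        env_effects.iloc[iesr_idx, env_effects.columns.get_loc(env)] = np.abs(
            rng.normal(config.env_effect_mean, config.env_effect_sd, size=len(iesr_idx))
        )
        env_effects.iloc[resr_idx, env_effects.columns.get_loc(env)] = -np.abs(
            rng.normal(config.env_effect_mean, config.env_effect_sd, size=len(resr_idx))
        )
    if config.regulon_environment in env_effects.columns and config.regulon_environment != config.baseline_environment:
        col = env_effects.columns.get_loc(config.regulon_environment)
        env_effects.iloc[regulon_idx, col] = np.abs(
            rng.normal(config.env_effect_mean, config.env_effect_sd, size=len(regulon_idx))
        )

    kinase_effects = pd.DataFrame(0.0, index=genes, columns=strains)
    master = dict(config.master_kinases)
    for kinase in config.kinases:
        kinase_effects[kinase] = _sparse_effects(
            rng, n, config.kinase_responsive_fraction,
            config.kinase_effect_mean, config.kinase_effect_sd,
        )
        sign = master.get(kinase)
        if sign:
            col = kinase_effects.columns.get_loc(kinase)
            kinase_effects.iloc[iesr_idx, col] = sign * np.abs(
                rng.normal(config.esr_kinase_effect, 0.25, size=len(iesr_idx))
            )
            kinase_effects.iloc[resr_idx, col] = -sign * np.abs(
                rng.normal(config.esr_kinase_effect, 0.25, size=len(resr_idx))
            )

    # TF target sets (promoters of these genes carry the TF's motif)
    tf_target_map: dict[str, GeneSet] = {}
    for t in range(config.n_tfs):
        size = min(config.tf_targets_per_tf, n)
        members = rng.choice(n, size=size, replace=False)
        name = f"TF{t + 1}"
        tf_target_map[name] = GeneSet(
            name=name,
            description="synthetic TF regulon",
            members=frozenset(genes[i] for i in members),
        )

    # sparse interactions on eligible (mutant, stress) cells
    missing = set(config.resolve_missing_cells())
    eligible_cells = [
        (k, e)
        for k in config.kinases
        for e in config.stress_environments
        if (k, e) not in missing
    ]
    interactions: dict[tuple[str, str, str], float] = {}
    if config.interaction_density > 0 and eligible_cells:
        hits = rng.random((n, len(eligible_cells))) < config.interaction_density
        signs = rng.choice([-1.0, 1.0], size=hits.shape)
        gi, ci = np.nonzero(hits)
        for g, c in zip(gi, ci):
            kinase, env = eligible_cells[c]
            interactions[(genes[g], kinase, env)] = (
                signs[g, c] * config.interaction_effect_size
            )
    # wired kinase->TF interaction sets
    for kinase, env, tf in config.kinase_tf_links:
        if (kinase, env) in missing:
            continue
        for gene in sorted(tf_target_map[tf].members):
            interactions[(gene, kinase, env)] = config.interaction_effect_size
    # uniform response attenuation: mutant sees alpha * env effect
    for kinase, env, alpha in config.attenuations:
        if (kinase, env) in missing:
            continue
        effects = env_effects[env]
        for gene in np.asarray(genes)[effects.values != 0.0]:
            interactions[(gene, kinase, env)] = (alpha - 1.0) * effects[gene]

    baseline = pd.Series(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n),
        index=genes, name="baseline_log2",
    )
    lo, hi = config.dispersion_range
    if hi == 0.0:
        disp = np.zeros(n)
    else:
        lo_eff = max(lo, 1e-12)
        disp = np.exp(rng.uniform(np.log(lo_eff), np.log(hi), size=n))
    dispersion = pd.Series(disp, index=genes, name="dispersion")

    return SimulationTruth(
        genes=genes,
        env_effects=env_effects,
        kinase_effects=kinase_effects,
        interaction_effects=interactions,
        baseline_log2=baseline,
        dispersion=dispersion,
        iesr=GeneSet("iESR", "pan-stress induced module", frozenset(np.asarray(genes)[iesr_idx])),
        resr=GeneSet("rESR", "pan-stress repressed module", frozenset(np.asarray(genes)[resr_idx])),
        regulon=GeneSet(
            "Hsf1-like_regulon",
            "dedicated-TF probe set responsive in one environment",
            frozenset(np.asarray(genes)[regulon_idx]),
        ),
        tf_target_map=tf_target_map,
        master_kinase_sign={k: s for k, s in master.items() if k in config.kinases},
    )


def build_annotation(config: SimulationConfig) -> pd.DataFrame:
    """The sample table implied by the design: WT replicates per environment
    plus one (or more) replicates per available mutant cell."""
    missing = set(config.resolve_missing_cells())
    rows = []
    for env in config.environments:
        for rep in range(1, config.wt_replicates + 1):
            rows.append((f"{config.baseline_strain}_{env}_rep{rep}",
                         config.baseline_strain, env, rep))
        for kinase in config.kinases:
            if env != config.baseline_environment and (kinase, env) in missing:
                continue
            for rep in range(1, config.mutant_replicates + 1):
                rows.append((f"{kinase}_{env}_rep{rep}", kinase, env, rep))
    ann = pd.DataFrame(rows, columns=["sample_id", "kinase", "environment", "replicate"])
    return ann.set_index("sample_id")


def simulate_counts(
    truth: SimulationTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the count matrix for the design.

    Per sample and gene the log2 mean is baseline + env effect + kinase
    effect + interaction + Gaussian noise; counts are negative binomial with
    variance ``mu + alpha * mu^2`` scaled by the sample's library factor.
    ``alpha == 0`` yields deterministic rounded means (the exact-additivity
    oracle).
    """
    rng = _rng(config.seed, "counts")
    ann = build_annotation(config)
    genes = truth.genes
    n_genes, n_samples = len(genes), len(ann)

    env_arr = truth.env_effects.loc[genes, ann["environment"]].to_numpy()
    kin_arr = truth.kinase_effects.loc[genes, ann["kinase"]].to_numpy()
    log2_mu = truth.baseline_log2.to_numpy()[:, None] + env_arr + kin_arr

    if truth.interaction_effects:
        gene_pos = {g: i for i, g in enumerate(genes)}
        cell_cols: dict[tuple[str, str], np.ndarray] = {}
        kin_env = list(zip(ann["kinase"], ann["environment"]))
        for (gene, kinase, env), delta in truth.interaction_effects.items():
            cell = (kinase, env)
            if cell not in cell_cols:
                cell_cols[cell] = np.array([i for i, ke in enumerate(kin_env) if ke == cell])
            cols = cell_cols[cell]
            if cols.size:
                log2_mu[gene_pos[gene], cols] += delta

    if config.noise_sd_log2 > 0:
        log2_mu = log2_mu + rng.normal(0.0, config.noise_sd_log2, size=log2_mu.shape)

    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    ann = ann.assign(library_factor=lib)  # ground truth for normalization tests
    mu = np.exp2(np.clip(log2_mu, -8.0, 24.0)) * lib[None, :]

    alpha = truth.dispersion.to_numpy()[:, None]
    counts = np.rint(mu).astype(np.int64)
    stochastic = (alpha[:, 0] > 0.0)
    if stochastic.any():
        a = alpha[stochastic]
        m = mu[stochastic]
        size_param = 1.0 / a
        p = size_param / (size_param + m)
        counts[stochastic] = rng.negative_binomial(size_param, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=ann.index)
    return counts_df, ann


def generate_motif_library(
    n_tfs: int,
    length: int = 10,
    seed: int = 0,
    consensus_count: int = 91,
    other_count: int = 3,
    pseudocount: float = 0.5,
) -> list[PWM]:
    """Sharp synthetic PWMs: one dominant base per column."""
    rng = _rng(seed, "motifs")
    library = []
    for t in range(n_tfs):
        consensus = rng.integers(0, 4, size=length)
        counts = np.full((4, length), float(other_count))
        counts[consensus, np.arange(length)] = float(consensus_count)
        library.append(PWM.from_counts(f"TF{t + 1}", counts, pseudocount=pseudocount))
    return library


def generate_promoters(
    truth: SimulationTruth,
    length: int = 500,
    motif_library: Sequence[PWM] | None = None,
    seed: int = 0,
    instance_mode: str = "consensus",
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> dict[str, str]:
    """I.i.d. background promoters with one planted motif instance per
    TF-target gene.

    ``instance_mode="consensus"`` plants the PWM's modal sequence (the
    deterministic oracle); ``"sample"`` draws each position from the PWM.
    """
    if instance_mode not in ("consensus", "sample"):
        raise ValueError("instance_mode must be 'consensus' or 'sample'")
    rng = _rng(seed, "promoters")
    motif_library = list(motif_library or [])
    by_name = {p.tf_name: p for p in motif_library}
    unknown = set(truth.tf_target_map) - set(by_name)
    if truth.tf_target_map and unknown and motif_library:
        raise ValueError(f"tf_target_map references PWMs absent from library: {sorted(unknown)}")
    for pwm in by_name.values():
        if pwm.length > length:
            raise ValueError(f"motif {pwm.tf_name!r} longer than promoter length {length}")

    comp = np.asarray(base_composition, dtype=float)
    comp = comp / comp.sum()
    bases = np.array(list("ACGT"))
    seqs = rng.choice(4, size=(len(truth.genes), length), p=comp)

    gene_pos = {g: i for i, g in enumerate(truth.genes)}
    for tf_name in sorted(truth.tf_target_map):
        pwm = by_name.get(tf_name)
        if pwm is None:
            continue
        L = pwm.length
        consensus_idx = pwm.matrix.argmax(axis=0)
        for gene in sorted(truth.tf_target_map[tf_name].members):
            start = int(rng.integers(0, length - L + 1))
            if instance_mode == "consensus":
                instance = consensus_idx
            else:
                instance = np.array(
                    [rng.choice(4, p=pwm.matrix[:, j]) for j in range(L)]
                )
            seqs[gene_pos[gene], start:start + L] = instance

    return {
        gene: "".join(bases[row]) for gene, row in zip(truth.genes, seqs)
    }


def generate_annotation_sets(
    truth: SimulationTruth,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 60),
    enriched_fraction: float = 0.2,
    seed: int = 0,
) -> list[GeneSet]:
    """Random annotation (GO-like) gene sets; a controlled fraction is
    constructed to overlap the planted interaction genes for enrichment
    power tests."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
    rng = _rng(seed, "sets")
    genes = np.asarray(truth.genes)
    igenes = sorted(truth.interaction_genes())
    n_enriched = int(round(enriched_fraction * n_sets))
    sets: list[GeneSet] = []
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        enriched = s < n_enriched and igenes
        if enriched:
            n_from_interactions = min(max(1, int(0.7 * size)), len(igenes))
            core = list(rng.choice(igenes, size=n_from_interactions, replace=False))
            pool = np.setdiff1d(genes, core)
            fill = list(rng.choice(pool, size=size - len(core), replace=False))
            members = core + fill
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets.append(
            GeneSet(
                name=f"SET{s + 1:03d}",
                description="interaction-enriched synthetic set" if enriched
                else "random synthetic set",
                members=frozenset(members),
            )
        )
    return sets


@dataclass
class SyntheticDataset:
    """One complete simulated study: inputs for every pipeline stage plus truth."""

    config: SimulationConfig
    truth: SimulationTruth
    counts: pd.DataFrame
    annotation: pd.DataFrame
    promoters: dict[str, str]
    motifs: list[PWM]
    annotation_sets: list[GeneSet]

    def signature_sets(self) -> list[GeneSet]:
        return [self.truth.iesr, self.truth.resr, self.truth.regulon]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    truth = generate_truth(config)
    counts, ann = simulate_counts(truth, config)
    motifs = generate_motif_library(config.n_tfs, config.motif_length, seed=config.seed)
    promoters = generate_promoters(
        truth, config.promoter_length, motifs, seed=config.seed
    )
    annotation_sets = generate_annotation_sets(truth, seed=config.seed)
    return SyntheticDataset(
        config=config,
        truth=truth,
        counts=counts,
        annotation=ann,
        promoters=promoters,
        motifs=motifs,
        annotation_sets=annotation_sets,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the full fixture bundle (TSV/GMT/FASTA/PFM + truth tables) and a
    manifest; returns the manifest mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": "counts.tsv",
        "annotation": "annotation.tsv",
        "promoters": "promoters.fasta",
        "motifs": "motifs.pfm",
        "signature_sets": "signatures.gmt",
        "annotation_sets": "annotation_sets.gmt",
        "truth_env_effects": "truth_env_effects.tsv",
        "truth_kinase_effects": "truth_kinase_effects.tsv",
        "truth_interactions": "truth_interactions.tsv",
        "truth_gene_params": "truth_gene_params.tsv",
    }
    write_count_matrix(
        dataset.counts, dataset.annotation,
        outdir / paths["counts"], outdir / paths["annotation"],
    )
    write_fasta_promoters(dataset.promoters, outdir / paths["promoters"])
    write_jaspar_pfm(dataset.motifs, outdir / paths["motifs"])
    write_gmt(dataset.signature_sets() + [
        gs for gs in dataset.truth.tf_target_map.values()
    ], outdir / paths["signature_sets"])
    write_gmt(dataset.annotation_sets, outdir / paths["annotation_sets"])
    truth = dataset.truth
    truth.env_effects.to_csv(outdir / paths["truth_env_effects"], sep="\t", index_label="gene")
    truth.kinase_effects.to_csv(outdir / paths["truth_kinase_effects"], sep="\t", index_label="gene")
    pd.DataFrame(
        [(g, k, e, d) for (g, k, e), d in sorted(truth.interaction_effects.items())],
        columns=["gene", "kinase", "environment", "log2_effect"],
    ).to_csv(outdir / paths["truth_interactions"], sep="\t", index=False)
    pd.DataFrame(
        {"baseline_log2": truth.baseline_log2, "dispersion": truth.dispersion}
    ).to_csv(outdir / paths["truth_gene_params"], sep="\t", index_label="gene")
    manifest = {
        "seed": dataset.config.seed,
        "n_samples": int(dataset.annotation.shape[0]),
        "n_genes": int(dataset.counts.shape[0]),
        "files": paths,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return paths
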