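"""From residual calls to a kinase -> transcription-factor network.

A TF's 40 target genes are wired to dysregulate when Hog1 is inhibited
under osmotic stress. The pipeline recovers this: the residual calls for
(Hog1-as, NaCl) are enriched for promoters carrying that TF's binding
motif, which becomes the single edge of the kinase-TF network.
"""

import kinstress as ks
from kinstress import preprocess as pp
from kinstress.decompose import group_calls
from kinstress.simulate import DEFAULT_KINASES

config = ks.SimulationConfig(
    n_genes=250,
    kinases=DEFAULT_KINASES[:6],
    environments=("YPD", "NaCl", "heat-shock", "menadione"),
    interaction_density=0.0,
    n_tfs=5,
    tf_targets_per_tf=40,
    kinase_tf_links=(("Hog1-as", "NaCl", "TF1"),),
    missing_cells=(),
    seed=2,
)
dataset = ks.generate_dataset(config)
factors = pp.size_factors(dataset.counts)
fc = pp.fold_changes(pp.normalize_log2(dataset.counts, factors), dataset.annotation)
fit = ks.fit_additive(fc, dataset.annotation)
calls, _, _ = ks.call_interactions(fit)
groups = group_calls(calls)
print(f"{len(calls)} residual calls in {len(groups)} (kinase, environment) groups")

universe = ks.GeneSet("universe", "all simulated genes", frozenset(dataset.counts.index))
results = ks.motif_enrichment(
    groups, dataset.promoters, dataset.motifs, universe,
    score_threshold_fraction=0.8, min_genes=10,
)
for r in sorted(results, key=lambda r: r.padj)[:5]:
    print(f"  {r.query_name} x {r.set_name}: overlap {r.overlap}/{r.query_size}, "
          f"adjusted p = {r.padj:.2e}")

edges, by_env = ks.build_kinase_tf_network(results, cutoff=0.05)
print("network edges (kinase --inhibition--> TF, per environment):")
for e in edges:
    print(f"  {e.kinase} -> {e.tf_name} in {e.environment} (padj {e.padj:.2e})")
# Exactly one edge is expected: the planted Hog1 -> TF1 link under NaCl.
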