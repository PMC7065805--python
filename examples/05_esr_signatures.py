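"""Stress-signature analysis: master regulators of the ESR.

The environmental stress response (ESR) has an induced module (iESR) and a
repressed module (rESR). The simulated PKA-like master kinase de-represses
the iESR and represses the rESR when inhibited; the planted antagonist
(a HOG-pathway-like kinase acting upstream with opposite sign) does the
reverse. The example prints the module medians per strain group and the
rank-sum tests against all other mutants, then clusters the fold-change
matrix the way perturbation heatmaps are ordered.
"""

import kinstress as ks
from kinstress import preprocess as pp
from kinstress.simulate import DEFAULT_KINASES

config = ks.SimulationConfig(
    n_genes=300,
    kinases=DEFAULT_KINASES[:6],
    environments=("YPD", "SDC", "heat-shock", "NaCl", "tunicamycin", "menadione"),
    iesr_size=40,
    resr_size=40,
    kinase_tf_links=(),
    seed=5,
)
dataset = ks.generate_dataset(config)
factors = pp.size_factors(dataset.counts)
expr = pp.normalize_log2(dataset.counts, factors)
fc_matched = pp.fold_changes(expr, dataset.annotation, pp.MATCHED_BASELINE)

dists = ks.esr_distributions(
    fc_matched, dataset.annotation,
    dataset.truth.iesr, dataset.truth.resr,
    focal_kinases=["Tpk123-as", "Pbs2-as"],
)
print("median log2 fold change of module genes (vs matched-environment WT):")
for d in dists:
    p = "" if d.skipped or d.group == "all-others" else f"  rank-sum p={d.rank_sum_p:.1e}"
    print(f"  {d.group:>10s} {d.set_name}: {d.median:+.2f} (IQR {d.iqr:.2f}){p}")
# Expected sign pattern: Tpk123-as iESR up / rESR down; Pbs2-as the mirror
# image; all other kinases near zero - the two regulate one pathway
# antagonistically.

assignment, order = ks.cluster_genes(
    pp.fold_changes(expr, dataset.annotation), n_clusters=4
)
sizes = assignment.value_counts().sort_index()
print(f"hierarchical clustering (1-Pearson, average linkage): "
      f"{dict(sizes)} genes per cluster")
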