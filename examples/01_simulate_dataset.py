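"""Generate a small synthetic kinase x environment perturbation study.

Builds a 300-gene dataset with 6 analog-sensitive kinase strains plus wild
type across 6 environments, then prints the design bookkeeping and a few
planted ground-truth facts. Every downstream example reuses this generator.
"""

import kinstress as ks
from kinstress.simulate import DEFAULT_KINASES

config = ks.SimulationConfig(
    n_genes=300,
    kinases=DEFAULT_KINASES[:6],
    environments=("YPD", "SDC", "heat-shock", "NaCl", "tunicamycin", "menadione"),
    iesr_size=40,
    resr_size=40,
    kinase_tf_links=(("Hog1-as", "NaCl", "TF1"),),
    missing_cells=(("Ypk1-as", "NaCl"),),
    seed=7,
)
dataset = ks.generate_dataset(config)

print(f"count matrix: {dataset.counts.shape[0]} genes x {dataset.counts.shape[1]} samples")
print(f"wild-type replicates per environment: {config.wt_replicates}")
print(f"missing mutant cells: {list(config.resolve_missing_cells())}")
print(f"planted interaction effects: {len(dataset.truth.interaction_effects)}")
print(f"iESR module size: {len(dataset.truth.iesr)}, rESR: {len(dataset.truth.resr)}")
print(f"TF target sets: { {tf: len(gs) for tf, gs in dataset.truth.tf_target_map.items()} }")

# The sample count is the design identity: strains x environments, minus
# missing cells, plus the wild-type replicates.
n_expected = 6 * 6 - 1 + 4 * 6
print(f"design check: {dataset.counts.shape[1]} == {n_expected}")
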