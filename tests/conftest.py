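import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import kinstress as ks
from kinstress import preprocess as pp
from kinstress.simulate import DEFAULT_KINASES

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

SMALL_KINASES = DEFAULT_KINASES[:6]
SMALL_ENVS = ("YPD", "SDC", "heat-shock", "NaCl", "tunicamycin", "menadione")


@pytest.fixture(scope="session")
def small_config():
    """A reduced but fully structured study: 6 kinases x 6 environments,
    planted TF link, one missing cell, one attenuated cell."""
    return ks.SimulationConfig(
        n_genes=150,
        kinases=SMALL_KINASES,
        environments=SMALL_ENVS,
        iesr_size=25,
        resr_size=25,
        regulon_size=15,
        n_tfs=3,
        tf_targets_per_tf=20,
        kinase_tf_links=(("Hog1-as", "NaCl", "TF1"),),
        attenuations=(("Sch9-as", "heat-shock", 0.4),),
        missing_cells=(("Ypk1-as", "NaCl"),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ks.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    factors = pp.size_factors(small_dataset.counts)
    expr = pp.normalize_log2(small_dataset.counts, factors)
    return {
        "factors": factors,
        "expr": expr,
        "fc_global": pp.fold_changes(expr, small_dataset.annotation),
        "fc_matched": pp.fold_changes(expr, small_dataset.annotation, pp.MATCHED_BASELINE),
    }


@pytest.fixture(scope="session")
def small_fit(small_matrices, small_dataset):
    return ks.fit_additive(small_matrices["fc_global"], small_dataset.annotation)


def exact_fold_changes(truth, ann):
    """Noise-free fold-change matrix implied by the truth: c_i + k_j per sample."""
    env = truth.env_effects.loc[:, ann["environment"]].to_numpy()
    kin = truth.kinase_effects.loc[:, ann["kinase"]].to_numpy()
    values = pd.DataFrame(env + kin, index=truth.env_effects.index, columns=ann.index)
    return pp.FoldChangeMatrix(
        values=values, baseline=pp.GLOBAL_BASELINE,
        baseline_strain="WT", baseline_environment="YPD",
    )


@pytest.fixture(scope="session")
def exact_additive(small_config):
    """Exactly additive data (no counts, no rounding) with its annotation."""
    cfg = ks.SimulationConfig(
        n_genes=80,
        kinases=SMALL_KINASES,
        environments=SMALL_ENVS,
        kinase_tf_links=(),
        missing_cells=(),
        seed=3,
    )
    truth = ks.generate_truth(cfg)
    from kinstress.simulate import build_annotation

    ann = build_annotation(cfg)
    return exact_fold_changes(truth, ann), ann, truth
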