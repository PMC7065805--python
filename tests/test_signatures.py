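"""Stress-signature distributions, gene-set response tests, set-level
residual scatter and gene clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kinstress as ks
from kinstress import preprocess as pp
from kinstress.decompose import AdditiveFit
from kinstress.io import GeneSet
from kinstress.signatures import (
    cluster_genes,
    esr_distributions,
    geneset_residual_scatter,
    geneset_response_test,
)


class TestESRDistributions:
    def test_master_and_antagonist_show_opposite_shifts(
        self, small_dataset, small_matrices
    ):
        """Inhibiting the PKA-like master induces the iESR and represses the
        rESR; the antagonist kinase shows the mirror image; both shifts are
        significant against the pooled remainder."""
        truth = small_dataset.truth
        dists = esr_distributions(
            small_matrices["fc_matched"], small_dataset.annotation,
            truth.iesr, truth.resr, ["Tpk123-as", "Pbs2-as"],
        )
        by_key = {(d.group, d.set_name): d for d in dists}
        ref_iesr = by_key[("all-others", "iESR")].median
        ref_resr = by_key[("all-others", "rESR")].median
        assert by_key[("Tpk123-as", "iESR")].median > ref_iesr + 0.5
        assert by_key[("Tpk123-as", "rESR")].median < ref_resr - 0.5
        assert by_key[("Pbs2-as", "iESR")].median < ref_iesr - 0.5
        assert by_key[("Pbs2-as", "rESR")].median > ref_resr + 0.5
        for focal in ("Tpk123-as", "Pbs2-as"):
            for set_name in ("iESR", "rESR"):
                assert by_key[(focal, set_name)].rank_sum_p < 1e-6

    def test_label_permutation_destroys_the_shift(
        self, small_dataset, small_matrices
    ):
        """With mutant labels shuffled among samples, the focal kinase is a
        random subset of the pool: no detectable location shift."""
        truth = small_dataset.truth
        rng = np.random.default_rng(17)
        mutant_idx = small_dataset.annotation.index[
            small_dataset.annotation["kinase"] != "WT"
        ]
        shifts = {"iESR": [], "rESR": []}
        # effect-size null averaged over permutations: any single permutation
        # can put several master-kinase samples into the pseudo-focal group
        # (values within a sample are correlated), but the expected
        # focal-vs-remainder shift is zero.
        for _ in range(30):
            ann = small_dataset.annotation.copy()
            ann.loc[mutant_idx, "kinase"] = rng.permutation(
                ann.loc[mutant_idx, "kinase"].to_numpy()
            )
            dists = esr_distributions(
                small_matrices["fc_matched"], ann, truth.iesr, truth.resr, ["Tpk123-as"],
            )
            by_key = {(d.group, d.set_name): d for d in dists}
            for set_name in ("iESR", "rESR"):
                shifts[set_name].append(
                    by_key[("Tpk123-as", set_name)].median
                    - by_key[("all-others", set_name)].median
                )
        for set_name in ("iESR", "rESR"):
            assert abs(np.mean(shifts[set_name])) < 0.15
            # and the planted (unpermuted) shift dwarfs the permutation spread
            real = esr_distributions(
                small_matrices["fc_matched"], small_dataset.annotation,
                truth.iesr, truth.resr, ["Tpk123-as"],
            )
            real_by = {(d.group, d.set_name): d for d in real}
            real_shift = (
                real_by[("Tpk123-as", set_name)].median
                - real_by[("all-others", set_name)].median
            )
            assert abs(real_shift) > 3 * np.std(shifts[set_name])

    def test_single_value_distribution_is_skipped(self, small_matrices, small_dataset):
        one_gene = GeneSet("tiny", "", frozenset([small_dataset.counts.index[0]]))
        ann = small_dataset.annotation
        keep = list(ann.index[(ann["kinase"] == "WT")][:2]) + [
            ann.index[ann["kinase"] == "Ste11-as"][0],
            ann.index[ann["kinase"] == "Hog1-as"][0],
        ]
        fc = pp.FoldChangeMatrix(
            small_matrices["fc_matched"].values[keep], pp.MATCHED_BASELINE, "WT", "YPD"
        )
        dists = esr_distributions(fc, ann.loc[keep], one_gene, one_gene, ["Ste11-as"])
        assert all(d.skipped for d in dists if d.group == "Ste11-as")


class TestGenesetResponseTest:
    def test_planted_attenuator_is_significant_and_negative(
        self, small_dataset, small_matrices
    ):
        kinase, env, alpha = small_dataset.config.attenuations[0]
        # the regulon responds in heat shock; the attenuated mutant damps it
        result = geneset_response_test(
            small_matrices["fc_matched"], small_dataset.annotation,
            small_dataset.truth.regulon, env,
        )
        assert result.loc[kinase, "padj"] < 0.01
        assert result.loc[kinase, "direction"] == "attenuation"

    def test_wild_type_like_mutant_is_not_significant(self):
        rng = np.random.default_rng(23)
        genes = pd.Index([f"g{i}" for i in range(12)], name="gene")
        cols = ["wt1", "wt2", "wt3", "wt4", "mut"]
        values = pd.DataFrame(rng.normal(0, 0.3, size=(12, 5)), index=genes, columns=cols)
        ann = pd.DataFrame(
            [(c, "WT" if c.startswith("wt") else "K1", "heat-shock", i + 1)
             for i, c in enumerate(cols)],
            columns=["sample_id", "kinase", "environment", "replicate"],
        ).set_index("sample_id")
        fc = pp.FoldChangeMatrix(values, pp.MATCHED_BASELINE, "WT", "YPD")
        gs = GeneSet("set", "", frozenset(genes))
        result = geneset_response_test(fc, ann, gs, "heat-shock")
        assert result.loc["K1", "pvalue"] > 0.05

    def test_too_small_set_is_rejected(self, small_dataset, small_matrices):
        tiny = GeneSet("tiny", "", frozenset(small_dataset.counts.index[:2]))
        with pytest.raises(ValueError, match="need >= 3"):
            geneset_response_test(
                small_matrices["fc_matched"], small_dataset.annotation, tiny, "NaCl"
            )


def _synthetic_fit(residuals, fitted=None):
    fitted = fitted if fitted is not None else residuals * 0.0
    return AdditiveFit(
        env_effects=pd.DataFrame(), kinase_effects=pd.DataFrame(),
        fitted=fitted, residuals=residuals, r2=pd.Series(dtype=float),
        ann=pd.DataFrame(), estimator="reference_plugin",
        baseline_strain="WT", baseline_environment="YPD",
    )


class TestGenesetResidualScatter:
    def test_single_gene_set_reduces_to_residual_z(self, small_fit):
        gene = small_fit.genes[3]
        gs = GeneSet("one", "", frozenset([gene]))
        pooled = small_fit.residuals.to_numpy().ravel()
        sigma = pooled[np.isfinite(pooled)].std()
        table = geneset_residual_scatter(small_fit, gs, sigma=sigma)
        expected = small_fit.residuals.loc[gene] / sigma
        assert np.allclose(table["set_z"], expected)

    def test_coordinated_shift_aggregates_with_sqrt_n(self):
        """A 1-sigma coordinated residual on a 20-gene set gives a set-level
        z near sqrt(20)."""
        rng = np.random.default_rng(11)
        genes = pd.Index([f"g{i}" for i in range(20)], name="gene")
        resid = pd.DataFrame(
            rng.normal(0, 1.0, size=(20, 50)), index=genes,
            columns=[f"s{i}" for i in range(50)],
        )
        resid["s0"] = 1.0  # the coordinated sample
        fit = _synthetic_fit(resid)
        gs = GeneSet("all", "", frozenset(genes))
        table = geneset_residual_scatter(fit, gs, sigma=1.0)
        assert table.loc["s0", "set_z"] == pytest.approx(np.sqrt(20), rel=0.01)
        assert bool(table.loc["s0", "flagged"])

    def test_null_sets_are_standard_normal(self):
        """Set-level z over independent null residuals matches N(0,1)
        (KS check on a large pool of samples)."""
        rng = np.random.default_rng(12)
        genes = pd.Index([f"g{i}" for i in range(25)], name="gene")
        resid = pd.DataFrame(
            rng.normal(0, 0.7, size=(25, 12_000)), index=genes,
            columns=[f"s{i}" for i in range(12_000)],
        )
        fit = _synthetic_fit(resid)
        gs = GeneSet("all", "", frozenset(genes))
        table = geneset_residual_scatter(fit, gs, sigma=0.7)
        ks = stats.kstest(table["set_z"], "norm").statistic
        assert ks < 0.02


class TestClusterGenes:
    def test_anticorrelated_modules_separate_perfectly(self):
        rng = np.random.default_rng(19)
        base = rng.normal(size=40)
        up = np.array([base + rng.normal(0, 0.1, size=40) for _ in range(10)])
        down = np.array([-base + rng.normal(0, 0.1, size=40) for _ in range(10)])
        values = pd.DataFrame(
            np.vstack([up, down]),
            index=pd.Index([f"u{i}" for i in range(10)] + [f"d{i}" for i in range(10)],
                           name="gene"),
        )
        assignment, order = cluster_genes(values, n_clusters=2)
        up_labels = set(assignment[[f"u{i}" for i in range(10)]])
        down_labels = set(assignment[[f"d{i}" for i in range(10)]])
        assert len(up_labels) == 1 and len(down_labels) == 1
        assert up_labels != down_labels
        assert sorted(order) == sorted(values.index)

    def test_duplicate_rows_share_a_cluster(self):
        rng = np.random.default_rng(20)
        values = pd.DataFrame(
            rng.normal(size=(6, 15)),
            index=pd.Index([f"g{i}" for i in range(6)], name="gene"),
        )
        values.loc["g5"] = values.loc["g0"]
        assignment, _ = cluster_genes(values, n_clusters=3)
        assert assignment["g0"] == assignment["g5"]

    def test_singletons_and_bounds(self):
        rng = np.random.default_rng(21)
        values = pd.DataFrame(
            rng.normal(size=(5, 10)),
            index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
        )
        assignment, _ = cluster_genes(values, n_clusters=5)
        assert assignment.nunique() == 5
        with pytest.raises(ValueError, match="exceeds"):
            cluster_genes(values, n_clusters=6)
        with pytest.raises(ValueError, match=">= 2"):
            cluster_genes(values, n_clusters=1)
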