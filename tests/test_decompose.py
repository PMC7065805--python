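"""The additive decomposition, its residual diagnostics and interaction calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kinstress as ks
from kinstress import preprocess as pp
from kinstress.decompose import (
    AdditiveFit,
    _cell_residuals,
    call_interactions,
    fit_additive,
    qq_normal,
    r2_distribution,
    residual_expression_association,
    residual_zscores,
)

from conftest import SMALL_ENVS, SMALL_KINASES, exact_fold_changes


def _toy_fc(delta=0.0):
    """One gene, two strains x two environments with a planted interaction."""
    c, k = 1.5, -0.8
    values = pd.DataFrame(
        {
            "wt_ypd": [0.0],
            "wt_env": [c],
            "mut_ypd": [k],
            "mut_env": [c + k + delta],
        },
        index=pd.Index(["g1"], name="gene"),
    )
    ann = pd.DataFrame(
        [
            ("wt_ypd", "WT", "YPD", 1),
            ("wt_env", "WT", "E", 1),
            ("mut_ypd", "K", "YPD", 1),
            ("mut_env", "K", "E", 1),
        ],
        columns=["sample_id", "kinase", "environment", "replicate"],
    ).set_index("sample_id")
    fc = pp.FoldChangeMatrix(values, pp.GLOBAL_BASELINE, "WT", "YPD")
    return fc, ann


class TestFitAdditive:
    def test_exactly_additive_data_has_zero_residuals(self, exact_additive):
        fc, ann, truth = exact_additive
        for estimator in ("reference_plugin", "joint_ols"):
            fit = fit_additive(fc, ann, estimator=estimator)
            assert np.abs(fit.residuals.to_numpy()).max() < 1e-9
            r2 = fit.r2.dropna()
            assert np.allclose(r2, 1.0)

    def test_estimators_coincide_on_complete_noise_free_design(self, exact_additive):
        fc, ann, truth = exact_additive
        plugin = fit_additive(fc, ann, estimator="reference_plugin")
        joint = fit_additive(fc, ann, estimator="joint_ols")
        assert np.allclose(plugin.env_effects, joint.env_effects, atol=1e-8)
        assert np.allclose(
            plugin.kinase_effects.fillna(0.0), joint.kinase_effects, atol=1e-8
        )

    def test_plugin_recovers_truth_exactly_noise_free(self, exact_additive):
        fc, ann, truth = exact_additive
        fit = fit_additive(fc, ann)
        assert np.allclose(fit.env_effects, truth.env_effects, atol=1e-10)
        assert np.allclose(fit.kinase_effects, truth.kinase_effects, atol=1e-10)

    def test_planted_interaction_lands_in_residual(self):
        fc, ann = _toy_fc(delta=0.7)
        fit = fit_additive(fc, ann)
        # hand algebra: all other cells fit exactly, the (K, E) cell carries delta
        assert fit.residuals.loc["g1", "mut_env"] == pytest.approx(0.7)
        assert fit.residuals.loc["g1", ["wt_ypd", "wt_env", "mut_ypd"]].abs().max() < 1e-12

    def test_plugin_baseline_cells_have_zero_residual(self, small_fit, small_dataset):
        """Under the plug-in estimator every (kinase, baseline-env) sample and
        every WT cell mean reproduces its own defining statistic exactly."""
        ann = small_dataset.annotation
        ypd_mut = ann.index[(ann["environment"] == "YPD") & (ann["kinase"] != "WT")]
        assert np.abs(small_fit.residuals[ypd_mut].to_numpy()).max() < 1e-10
        cells = _cell_residuals(small_fit)
        wt_cols = cells.columns.get_level_values("kinase") == "WT"
        assert np.abs(cells.loc[:, wt_cols].to_numpy()).max() < 1e-10

    def test_plugin_kinase_effect_is_local(self, exact_additive):
        """Dropping one kinase's samples never changes another's plug-in k."""
        fc, ann, truth = exact_additive
        full = fit_additive(fc, ann)
        keep = ann.index[ann["kinase"] != "Hog1-as"]
        sub_fc = pp.FoldChangeMatrix(
            fc.values[keep], fc.baseline, fc.baseline_strain, fc.baseline_environment
        )
        sub = fit_additive(sub_fc, ann.loc[keep])
        assert np.allclose(
            full.kinase_effects["Sch9-as"], sub.kinase_effects["Sch9-as"], atol=1e-12
        )

    def test_disconnected_design_is_rejected_for_joint_ols(self):
        values = pd.DataFrame(
            {"a": [0.0], "b": [1.0]}, index=pd.Index(["g1"], name="gene")
        )
        ann = pd.DataFrame(
            [("a", "WT", "YPD", 1), ("b", "K", "E", 1)],
            columns=["sample_id", "kinase", "environment", "replicate"],
        ).set_index("sample_id")
        fc = pp.FoldChangeMatrix(values, pp.GLOBAL_BASELINE, "WT", "YPD")
        with pytest.raises(ValueError, match="disconnected"):
            fit_additive(fc, ann, estimator="joint_ols")

    def test_estimators_agree_closely_on_simulated_counts(
        self, small_fit, small_matrices, small_dataset
    ):
        joint = fit_additive(
            small_matrices["fc_global"], small_dataset.annotation, estimator="joint_ols"
        )
        envs = [e for e in SMALL_ENVS if e != "YPD"]
        r = np.corrcoef(
            small_fit.env_effects[envs].to_numpy().ravel(),
            joint.env_effects[envs].to_numpy().ravel(),
        )[0, 1]
        assert r > 0.98


class TestR2Distribution:
    def test_noise_free_mean_is_one(self, exact_additive):
        fc, ann, _ = exact_additive
        fit = fit_additive(fc, ann)
        summary = r2_distribution(fit, min_genes=50)
        assert summary.mean == pytest.approx(1.0, abs=1e-9)

    def test_r2_decreases_with_noise(self):
        means = []
        for noise in (0.1, 0.6):
            cfg = ks.SimulationConfig(
                n_genes=150, kinases=SMALL_KINASES, environments=SMALL_ENVS,
                noise_sd_log2=noise, kinase_tf_links=(), seed=21,
            )
            ds = ks.generate_dataset(cfg)
            factors = pp.size_factors(ds.counts)
            fc = pp.fold_changes(pp.normalize_log2(ds.counts, factors), ds.annotation)
            fit = fit_additive(fc, ds.annotation)
            means.append(r2_distribution(fit).mean)
        assert means[0] > means[1]


class TestResidualZScores:
    def test_zero_centered_and_unit_scale(self, small_fit):
        z, sigma, mean = residual_zscores(small_fit)
        zz = z.to_numpy().ravel()
        assert np.mean(zz) == pytest.approx(0.0, abs=1e-9)
        assert np.std(zz) == pytest.approx(1.0, rel=1e-9)
        assert sigma > 0

    def test_mad_matches_sd_on_gaussian_pool(self):
        """1.4826 * MAD is a consistent sd estimator for Gaussian residuals."""
        rng = np.random.default_rng(0)
        resid = pd.DataFrame(rng.normal(0, 0.4, size=(200, 100)))
        fit = AdditiveFit(
            env_effects=pd.DataFrame(), kinase_effects=pd.DataFrame(),
            fitted=resid * 0.0, residuals=resid, r2=pd.Series(dtype=float),
            ann=pd.DataFrame(), estimator="reference_plugin",
            baseline_strain="WT", baseline_environment="YPD",
        )
        _, sd_sigma, _ = residual_zscores(fit, "global_sd")
        _, mad_sigma, _ = residual_zscores(fit, "global_mad")
        assert abs(mad_sigma / sd_sigma - 1.0) < 0.05


class TestQQNormal:
    def test_standard_normal_sample_lies_on_the_line(self):
        rng = np.random.default_rng(1)
        theo, emp, within = qq_normal(rng.standard_normal(100_000), band=0.1)
        bulk = slice(1000, -1000)
        assert np.abs(emp[bulk] - theo[bulk]).max() < 0.05
        assert within > 0.98

    def test_heavy_tailed_mixture_leaves_the_line_in_the_tails(self):
        rng = np.random.default_rng(2)
        n = 50_000
        scale = np.where(rng.random(n) < 0.05, 3.0, 1.0)
        z = rng.standard_normal(n) * scale
        z = (z - z.mean()) / z.std()
        theo, emp, _ = qq_normal(z)
        assert emp[-1] > theo[-1] + 0.5
        assert emp[0] < theo[0] - 0.5

    def test_constant_input_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            qq_normal(np.zeros(2000))


class TestResidualExpressionAssociation:
    def _fit_with_residuals(self, resid):
        return AdditiveFit(
            env_effects=pd.DataFrame(), kinase_effects=pd.DataFrame(),
            fitted=resid * 0.0, residuals=resid, r2=pd.Series(dtype=float),
            ann=pd.DataFrame(), estimator="reference_plugin",
            baseline_strain="WT", baseline_environment="YPD",
        )

    def test_homoskedastic_null_has_low_correlation(self):
        rng = np.random.default_rng(3)
        resid = pd.DataFrame(rng.normal(size=(400, 300)))
        expr = pd.Series(rng.normal(8, 1.5, size=400), index=resid.index)
        assoc = residual_expression_association(self._fit_with_residuals(resid), expr)
        assert abs(assoc.correlation) < 0.05
        assert not assoc.degenerate

    def test_planted_mean_dependent_noise_is_detected(self):
        rng = np.random.default_rng(4)
        expr = pd.Series(np.linspace(4, 12, 300))
        resid = pd.DataFrame(
            rng.normal(size=(300, 100)) * (expr.to_numpy()[:, None] / 8.0) ** 2
        )
        assoc = residual_expression_association(self._fit_with_residuals(resid), expr)
        assert assoc.correlation > 0.2

    def test_constant_expression_is_flagged(self):
        rng = np.random.default_rng(5)
        resid = pd.DataFrame(rng.normal(size=(50, 20)))
        expr = pd.Series(7.0, index=resid.index)
        assoc = residual_expression_association(self._fit_with_residuals(resid), expr)
        assert assoc.degenerate and np.isnan(assoc.correlation)


class TestCallInteractions:
    def test_infinite_threshold_calls_nothing(self, small_fit):
        calls, _, _ = call_interactions(small_fit, threshold=np.inf)
        assert calls == []

    def test_strongly_planted_interactions_are_called_with_sign(self):
        cfg = ks.SimulationConfig(
            n_genes=150, kinases=SMALL_KINASES, environments=SMALL_ENVS,
            interaction_density=0.01, interaction_effect_size=3.0,
            kinase_tf_links=(), seed=13,
        )
        ds = ks.generate_dataset(cfg)
        factors = pp.size_factors(ds.counts)
        fc = pp.fold_changes(pp.normalize_log2(ds.counts, factors), ds.annotation)
        fit = fit_additive(fc, ds.annotation)
        calls, _, _ = call_interactions(fit)
        called = {(c.gene, c.kinase, c.environment): c.sign for c in calls}
        planted = ds.truth.interaction_effects
        recovered = [key for key in planted if key in called]
        assert len(recovered) / len(planted) >= 0.9
        for key in recovered:
            assert called[key] == np.sign(planted[key])

    def test_calls_sorted_by_magnitude(self, small_fit):
        calls, _, _ = call_interactions(small_fit)
        mags = [abs(c.residual_z) for c in calls]
        assert mags == sorted(mags, reverse=True)
        assert all(
            not (c.kinase == "WT" and c.environment == "YPD") for c in calls
        )
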