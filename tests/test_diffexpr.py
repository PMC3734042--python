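import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from mirimpact.diffexpr import (
    VariancePrior,
    detection_filter,
    fit_variance_prior,
    group_stats,
    inverse_trigamma,
    moderated_t_test,
    qvalues,
    student_t_test,
)
from mirimpact.errors import EstimationError, InputError
from mirimpact.io import DetectionMatrix


class TestDetectionFilter:
    def _det(self, matrix, n_case):
        m = np.asarray(matrix, bool)
        samples = [f"s{i}" for i in range(m.shape[1])]
        groups = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
        det = DetectionMatrix([f"f{i}" for i in range(m.shape[0])], samples, m)
        return det, groups

    def test_fully_detected_feature_kept(self):
        det, groups = self._det(np.ones((1, 6)), n_case=3)
        assert detection_filter(det, groups) == {"f0"}

    def test_exact_half_in_one_group_is_removed(self):
        # 5/10 cases (exactly 50%) fails the strict >50% rule even with 9/9 controls
        row = [1] * 5 + [0] * 5 + [1] * 9
        det, groups = self._det([row], n_case=10)
        assert detection_filter(det, groups) == set()

    def test_empty_group_rejected(self):
        det, _ = self._det(np.ones((1, 4)), n_case=2)
        with pytest.raises(InputError):
            detection_filter(det, {f"s{i}": "case" for i in range(4)})

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(42)
        m = rng.random((200, 20)) < 0.6
        det, groups = self._det(m, n_case=11)
        expected = set()
        for i in range(200):
            case = m[i, :11]
            ctrl = m[i, 11:]
            if case.mean() > 0.5 and ctrl.mean() > 0.5:
                expected.add(f"f{i}")
        assert detection_filter(det, groups) == expected


class TestGroupStats:
    def test_hand_cases(self, expr_factory):
        em = expr_factory([[1.0, 1.0], [2.0, 2.0]], [[0.0, 0.0], [2.0, 2.0]])
        gs = group_stats(em)
        assert gs.loc["f0", "fold_change"] == pytest.approx(2.0)
        assert gs.loc["f0", "s_sq"] == 0.0
        assert gs.loc["f1", "fold_change"] == pytest.approx(1.0)
        assert gs.loc["f1", "log2_fc"] == 0.0

    def test_fold_change_matches_direct_recomputation(self, expr_factory):
        rng = np.random.default_rng(1)
        case, ctrl = rng.normal(size=(100, 5)), rng.normal(size=(100, 6))
        gs = group_stats(expr_factory(case, ctrl))
        direct = 2.0 ** (case.mean(axis=1) - ctrl.mean(axis=1))
        np.testing.assert_allclose(gs["fold_change"].to_numpy(), direct, atol=1e-12, rtol=0)

    def test_single_sample_group_rejected(self, expr_factory):
        with pytest.raises(InputError):
            group_stats(expr_factory([[1.0]], [[0.0, 1.0]]))


def test_fold_change_reciprocal_property(expr_factory):
    rng = np.random.default_rng(9)
    case, ctrl = rng.normal(size=(50, 4)), rng.normal(size=(50, 5))
    fwd = group_stats(expr_factory(case, ctrl))["fold_change"].to_numpy()
    rev = group_stats(expr_factory(ctrl, case))["fold_change"].to_numpy()
    np.testing.assert_allclose(fwd * rev, 1.0, atol=1e-12)


class TestStudentT:
    def test_identical_groups_give_t0_p1(self, expr_factory):
        em = expr_factory([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        res = student_t_test(em)
        assert res["t"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_hand_computed_pooled_t(self, expr_factory):
        # case {2,3,4} vs control {0,1,2}: pooled s^2=1, t = 2/sqrt(2/3)
        em = expr_factory([[2.0, 3.0, 4.0]], [[0.0, 1.0, 2.0]])
        res = student_t_test(em)
        assert res["t"].iloc[0] == pytest.approx(2.449, abs=5e-4)
        assert res["p_value"].iloc[0] == pytest.approx(0.0705, abs=5e-5)

    def test_zero_variance_separated_groups_flagged_degenerate(self, expr_factory):
        em = expr_factory([[1.0, 1.0]], [[0.0, 0.0]])
        res = student_t_test(em)
        assert res["degenerate"].iloc[0]
        assert np.isinf(res["t"].iloc[0])

    def test_null_pvalues_are_uniform(self, null_study):
        res = student_t_test(null_study.mrna_expr)
        assert stats.kstest(res["p_value"], "uniform").pvalue > 0.01


class TestVariancePrior:
    def test_inverse_trigamma_round_trip(self):
        for y in np.geomspace(1e-4, 10, 40):
            x = inverse_trigamma(y)
            assert special.polygamma(1, x) == pytest.approx(y, abs=1e-8, rel=1e-8)

    def test_recovers_planted_hyperparameters(self):
        d0_true, s0_true, df = 4.0, 0.05, 17.0
        est_d0, est_s0 = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 2000)
            s_sq = sigma2 * rng.chisquare(df, 2000) / df
            prior = fit_variance_prior(s_sq, df)
            est_d0.append(prior.d0)
            est_s0.append(prior.s0_sq)
        assert abs(np.median(est_d0) - d0_true) / d0_true < 0.5
        assert abs(np.median(est_s0) - s0_true) / s0_true < 0.25

    def test_constant_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(50, 0.3), 10.0)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3, rel=0.2)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(EstimationError):
            fit_variance_prior(np.zeros(100), 10.0)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self, expr_factory):
        rng = np.random.default_rng(3)
        em = expr_factory(rng.normal(size=(1000, 6)), rng.normal(size=(1000, 5)))
        gs = group_stats(em)
        ordinary = student_t_test(em)
        moderated = moderated_t_test(gs, VariancePrior(d0=0.0, s0_sq=1.0))
        np.testing.assert_allclose(moderated["t"], ordinary["t"], atol=1e-10, rtol=0)
        np.testing.assert_allclose(moderated["p_value"], ordinary["p_value"], atol=1e-10, rtol=0)

    def test_d0_infinite_uses_prior_scale_exactly(self, expr_factory):
        em = expr_factory([[1.0, 2.0], [1.0, 1.0]], [[0.0, 1.0], [1.0, 1.0]])
        gs = group_stats(em)
        res = moderated_t_test(gs, VariancePrior(d0=np.inf, s0_sq=0.25))
        expected_t = 1.0 / np.sqrt(0.25 * (0.5 + 0.5))
        assert res["t"].iloc[0] == pytest.approx(expected_t, rel=1e-12)
        assert res["t"].iloc[1] == 0.0
        assert res["p_value"].iloc[1] == 1.0

    def test_matches_independent_linear_model_implementation(self, tmp_path, expr_factory):
        """Cross-check hyperparameters, t and p against limma's eBayes."""
        rng = np.random.default_rng(11)
        sigma2 = 0.05 * 4 / rng.chisquare(4, 80)
        case = rng.normal(7, 1.5, 80)[:, None] + rng.standard_normal((80, 5)) * np.sqrt(sigma2)[:, None]
        ctrl = case.mean(axis=1, keepdims=True) + rng.standard_normal((80, 5)) * np.sqrt(sigma2)[:, None]
        em = expr_factory(case, ctrl)
        gs = group_stats(em)
        prior = fit_variance_prior(gs["s_sq"].to_numpy(), gs["df"].to_numpy())
        mine = moderated_t_test(gs, prior)
        x_path = tmp_path / "x.csv"
        em.to_frame().to_csv(x_path, index=False)
        r_code = f"""
suppressMessages(library(limma))
x <- as.matrix(read.csv("{x_path}"))
design <- cbind(Intercept=1, case=c(rep(1,5), rep(0,5)))
fit <- eBayes(lmFit(x, design))
write.csv(data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"],
                     d0=fit$df.prior, s0=fit$s2.prior), "{tmp_path}/ref.csv", row.names=FALSE)
"""
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv")
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(mine["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(mine["p_value"], ref["p"], rtol=1e-6)


def test_moderation_improves_power_at_matched_type_one_error():
    """With heteroscedastic gene variances, the moderated test detects at
    least as many planted DE genes as the ordinary t at the p-value cutoff
    matching a 5% empirical type-I rate on the null genes."""
    from mirimpact.simulate import SimulationConfig, generate_study

    power_ordinary, power_moderated = [], []
    for seed in range(6):
        cfg = SimulationConfig(
            n_gene=2000, n_mirna=10, n_de_mirna=0, n_de_gene_independent=200,
            repression_transfer_max=0.0, independent_effect_range=(0.2, 0.6),
            targets_per_mirna_mean=30, n_go_terms=5, n_enriched_terms=0, seed=seed,
        )
        study = generate_study(cfg)
        planted = set(study.truth.de_genes_independent)
        is_planted = np.array([f in planted for f in study.mrna_expr.feature_ids])
        gs = group_stats(study.mrna_expr)
        prior = fit_variance_prior(gs["s_sq"].to_numpy(), gs["df"].to_numpy())
        for res, bag in (
            (student_t_test(study.mrna_expr), power_ordinary),
            (moderated_t_test(gs, prior), power_moderated),
        ):
            p = res["p_value"].to_numpy()
            cutoff = np.quantile(p[~is_planted], 0.05)
            bag.append((p[is_planted] < cutoff).mean())
    assert np.mean(power_moderated) >= np.mean(power_ordinary)


class TestQvalues:
    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(qvalues(np.ones(5)), np.ones(5))

    def test_hand_computation_at_lambda_half(self):
        q = qvalues(np.array([0.01, 0.02, 0.9, 0.95]), lam=0.5)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.95, 0.95], atol=1e-12)

    def test_equals_benjamini_hochberg_when_pi0_is_one(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=500)
        q = qvalues(p, lam=0.0)  # lam=0 forces pi0 = 1
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p_and_bounded_below(self, plist):
        p = np.array(plist)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        m = len(p)
        pi0 = min(1.0, (p > 0.5).sum() / (m * 0.5))
        assert np.all(q >= pi0 * p - 1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            qvalues(np.array([]))

    def test_null_discovery_fraction_controlled(self):
        fracs = [
            (qvalues(np.random.default_rng(seed).uniform(size=2000)) < 0.05).mean()
            for seed in range(20)
        ]
        assert np.mean(fracs) <= 0.05
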