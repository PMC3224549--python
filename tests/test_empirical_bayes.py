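import shutil
import subprocess
import warnings

import numpy as np
import pytest
from scipy import stats

import dexval as dx
from dexval.empirical_bayes import (
    PValueVector,
    estimate_effect_prior_var,
    log_odds_de,
)


def _paired(rows):
    rows = np.asarray(rows, dtype=float)
    return dx.GroupedExpression([f"g{i}" for i in range(rows.shape[0])],
                                np.zeros_like(rows), rows, paired=True)


class TestTPValues:
    def test_zero_spread_masked(self):
        with pytest.warns(UserWarning, match="zero variance"):
            p = dx.t_pvalues(_paired([[1.0, 1.0, 1.0]]))
        assert np.isnan(p.p[0])

    def test_identical_groups_give_half(self):
        data = dx.GroupedExpression(["g"], np.array([[1.0, 2.0, 3.0]]),
                                    np.array([[1.0, 2.0, 3.0]]), False)
        assert dx.t_pvalues(data).p[0] == pytest.approx(0.5)

    def test_symmetric_null_mean_half(self):
        rng = np.random.default_rng(0)
        p = dx.t_pvalues(_paired(rng.standard_normal((2000, 6))))
        assert abs(np.nanmean(p.p) - 0.5) < 0.02

    def test_matches_scipy_one_sample(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(0.5, 1.0, size=(50, 5))
        p = dx.t_pvalues(_paired(rows)).p
        ref = stats.ttest_1samp(rows, 0.0, axis=1, alternative="greater").pvalue
        np.testing.assert_allclose(p, ref, rtol=1e-10)

    def test_matches_scipy_two_sample(self):
        rng = np.random.default_rng(4)
        x, xp = rng.normal(size=(30, 5)), rng.normal(0.4, 1, size=(30, 6))
        data = dx.GroupedExpression([f"g{i}" for i in range(30)], x, xp, False)
        ref = stats.ttest_ind(xp, x, axis=1, alternative="greater").pvalue
        np.testing.assert_allclose(dx.t_pvalues(data).p, ref, rtol=1e-10)


class TestWilcoxon:
    def test_signed_rank_exact_enumeration(self):
        # all positive d with n = 3: only 1 of the 2^3 sign assignments has
        # a rank sum this large, so one-sided p = 1/8
        p = dx.wilcoxon_pvalues(_paired([[1.0, 2.0, 3.0]]))
        assert p.p[0] == pytest.approx(1 / 8)

    def test_rank_sum_exact_enumeration(self):
        # x' entirely above x with n = n' = 2: 1 of C(4,2) = 6 labelings
        data = dx.GroupedExpression(["g"], np.array([[1.0, 2.0]]),
                                    np.array([[3.0, 4.0]]), False)
        assert dx.wilcoxon_pvalues(data).p[0] == pytest.approx(1 / 6)

    def test_all_zero_differences_masked(self):
        x = np.array([[1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            p = dx.wilcoxon_pvalues(dx.GroupedExpression(["g"], x, x.copy(), True))
        assert np.isnan(p.p[0])


class TestModeratedT:
    def test_d0_zero_limit_recovers_classical_t(self):
        rng = np.random.default_rng(7)
        rows = rng.normal(0, 1, size=(100, 5))
        data = _paired(rows)
        fit = dx.fit_moderated_t(data, d0=1e-12, s02=1.0)
        classical = dx.t_pvalues(data).p
        np.testing.assert_allclose(fit.pvalues, classical, rtol=1e-4)

    def test_d0_infinity_limit_is_z_test(self):
        rng = np.random.default_rng(8)
        rows = rng.normal(0, 1, size=(100, 5))
        fit = dx.fit_moderated_t(_paired(rows), d0=1e6, s02=0.5)
        z = fit.dhat / np.sqrt(0.5 / 5)
        np.testing.assert_allclose(fit.pvalues, stats.norm.sf(z), rtol=1e-3)

    def test_identical_variances_shrink_to_themselves(self):
        # every gene with the same spread: posterior variance == that spread
        base = np.array([-1.0, 0.0, 1.0, 0.0])
        rows = np.stack([base + mu for mu in np.linspace(-2, 2, 50)])
        fit = dx.fit_moderated_t(_paired(rows))
        np.testing.assert_allclose(fit.s2_post, fit.s2, rtol=1e-6)

    def test_hyperparameter_recovery(self, paired_data_pi09):
        data, _ = paired_data_pi09  # generated with d0 = 4, s0^2 = 0.05
        fit = dx.fit_moderated_t(data)
        assert abs(fit.d0 - 4.0) / 4.0 < 0.25
        assert abs(fit.s02 - 0.05) / 0.05 < 0.10

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(size=(500, 6))
        fit = dx.fit_moderated_t(_paired(rows))
        lo = np.minimum(fit.s2, fit.s02) - 1e-12
        hi = np.maximum(fit.s2, fit.s02) + 1e-12
        assert np.all((fit.s2_post >= lo) & (fit.s2_post <= hi))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_limma_reference(self, tmp_path):
        """The hierarchical-variance fit is a port of limma's moment matching;
        hyperparameters and moderated t must agree with the R original."""
        data, _ = dx.generate(dx.SimulationConfig(m=300, n=5, n_prime=5,
                                                  pi0=0.85, paired=True, seed=7))
        d = data.differences()
        dpath = tmp_path / "d.tsv"
        np.savetxt(dpath, d, delimiter="\t")
        out = tmp_path / "limma.tsv"
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'd <- as.matrix(read.table("{dpath}", sep="\\t"))\n'
            'fit <- eBayes(lmFit(d, design=matrix(1, ncol(d), 1)))\n'
            'cat(fit$df.prior, fit$s2.prior, "\\n")\n'
            f'write.table(fit$t, "{out}", sep="\\t", row.names=FALSE, col.names=FALSE)\n'
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        d0_r, s02_r = map(float, res.stdout.split()[:2])
        fit = dx.fit_moderated_t(data)
        assert fit.d0 == pytest.approx(d0_r, rel=1e-4)
        assert fit.s02 == pytest.approx(s02_r, rel=1e-4)
        t_r = np.loadtxt(out)
        np.testing.assert_allclose(fit.tstat, t_r, rtol=1e-8)

    def test_too_few_genes_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            dx.fit_moderated_t(_paired([[1.0, 1.0, 1.0]]))


class TestPi0Iteration:
    def test_self_consistent_start_fixed_point(self, paired_data_pi09):
        data, _ = paired_data_pi09
        fit = dx.fit_moderated_t(data)
        # force log-odds constant at log(1/9): update is 0.9 immediately
        state = dx.iterate_pi0(fit, start=0.9, v0=None)
        assert state.converged and state.trajectory[0] == 0.9

    def test_recovers_null_proportion(self, paired_data_pi09):
        data, _ = paired_data_pi09
        state = dx.iterate_pi0(dx.fit_moderated_t(data))
        assert 0.8 <= state.pi0 <= 1.0

    def test_trajectory_deterministic(self, paired_data_pi09):
        data, _ = paired_data_pi09
        fit = dx.fit_moderated_t(data)
        s1, s2 = dx.iterate_pi0(fit), dx.iterate_pi0(fit)
        assert s1.trajectory == s2.trajectory

    def test_stops_on_sign_change(self, paired_data_pi09):
        data, _ = paired_data_pi09
        fit = dx.fit_moderated_t(data)
        state = dx.iterate_pi0(fit, tol=0.0)  # only sign change / exact fixpoint stop
        diffs = np.diff(state.trajectory)
        assert state.converged
        assert (diffs[-1] == 0.0 or diffs[-1] * diffs[-2] < 0
                or state.iterations <= 2)


class TestLimmaProb:
    @pytest.mark.parametrize("omega,expected", [(1.0, 0.5), (9.0, 0.1)])
    def test_odds_algebra(self, paired_data_pi09, omega, expected):
        data, _ = paired_data_pi09
        fit = dx.fit_moderated_t(data)
        state = dx.iterate_pi0(fit)
        lo = log_odds_de(fit, state.pi0, state.v0)
        pi = dx.limma_prob(fit, state)
        np.testing.assert_allclose(pi, 1 / (1 + np.exp(lo)), atol=1e-12)
        assert 1 / (1 + omega) == pytest.approx(expected)


class TestLocalFdr:
    def test_pure_null_high_fdr(self):
        rng = np.random.default_rng(11)
        p = PValueVector(stats.norm.sf(rng.standard_normal(10_000)))
        fit = dx.local_fdr(p, "theoretical")
        assert np.nanmedian(fit.fdr) >= 0.9
        assert fit.pi0 > 0.9

    def test_shifted_genes_get_lower_fdr(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal(10_000)
        z[:1000] += 3.0
        fit = dx.local_fdr(PValueVector(stats.norm.sf(z)), "theoretical")
        assert np.nanmean(fit.fdr[:1000]) < np.nanmean(fit.fdr[1000:])

    def test_empirical_null_recovers_shifted_scaled_null(self):
        rng = np.random.default_rng(13)
        z = 0.5 + 1.4 * rng.standard_normal(20_000)
        fit = dx.local_fdr(PValueVector(stats.norm.sf(z)), "empirical")
        assert abs(fit.null_center - 0.5) < 0.15
        assert abs(fit.null_scale - 1.4) < 0.15

    def test_output_capped_to_unit_interval(self):
        rng = np.random.default_rng(14)
        fit = dx.local_fdr(PValueVector(rng.random(500)), "theoretical")
        ok = np.isfinite(fit.fdr)
        assert np.all((fit.fdr[ok] >= 0) & (fit.fdr[ok] <= 1))

    def test_too_few_genes_raise(self):
        with pytest.raises(ValueError, match=">= 200"):
            dx.local_fdr(PValueVector(np.linspace(0.01, 0.99, 50)))

    def test_gene_relabeling_equivariance(self):
        rng = np.random.default_rng(15)
        p = rng.random(2000)
        fdr = dx.local_fdr(PValueVector(p), "theoretical").fdr
        perm = rng.permutation(2000)
        fdr_perm = dx.local_fdr(PValueVector(p[perm]), "theoretical").fdr
        np.testing.assert_allclose(fdr_perm, fdr[perm], rtol=1e-10)


class TestEbSelector:
    def test_unknown_variant(self, paired_data_pi09):
        with pytest.raises(ValueError, match="unknown"):
            dx.eb_selector(paired_data_pi09[0], "mystery")

    @pytest.mark.parametrize("variant", dx.EB_VARIANTS)
    def test_nulls_score_higher_pi_than_alternatives(self, paired_data_pi09,
                                                     variant):
        data, truth = paired_data_pi09
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi = dx.eb_selector(data, variant)
        assert (np.nanmean(pi[truth.is_null])
                > np.nanmean(pi[~truth.is_null]))

    def test_pure_null_mean_pi_above_half(self):
        data, _ = dx.generate(dx.SimulationConfig(m=2000, n=6, n_prime=6,
                                                  pi0=1.0, paired=True, seed=21))
        for variant in ("t_locfdr", "modt_locfdr", "modt_limma"):
            pi = dx.eb_selector(data, variant)
            assert np.nanmean(pi) > 0.5, variant
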