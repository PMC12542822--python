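"""Two-group fits, empirical-Bayes moderation, BH adjustment, calls."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from phoskit import (
    ConfigError,
    DegenerateDataError,
    Design,
    ModerationPrior,
    adjust_bh,
    call_significant,
    estimate_prior,
    fit_feature_model,
    moderate,
    run_differential,
)
from phoskit.diffstats import fit_all_features, trigamma_inverse

from oracles import bh_step_up, pooled_t, sample_variances


class TestFeatureFit:
    def test_noise_free_difference(self, design6):
        beta, s2, d = fit_feature_model([0, 0, 0, 1, 1, 1], design6)
        assert (beta, s2, d) == (1.0, 0.0, 4)

    def test_hand_computed_pooled_fit(self, design6):
        beta, s2, d = fit_feature_model([0.1, 0.2, 0.3, -0.9, -1.0, -1.1], design6)
        assert beta == pytest.approx(-1.2)
        assert s2 == pytest.approx(0.01)
        assert d == 4
        t_mod, p, _ = moderate(beta, s2, d, ModerationPrior(1.0, 1.0), 2 / 3, d0_override=0.0)
        t_ref, p_ref, _ = pooled_t([0.1, 0.2, 0.3], [-0.9, -1.0, -1.1])
        assert t_mod[0] == pytest.approx(t_ref)
        assert t_mod[0] == pytest.approx(-14.6969, abs=1e-4)
        assert p[0] == pytest.approx(p_ref)

    def test_missing_value_reduces_df(self, design6):
        _, _, d = fit_feature_model([0.1, 0.2, 0.3, -0.9, np.nan, -1.1], design6)
        assert d == 3

    def test_insufficient_group_raises(self, design6):
        with pytest.raises(DegenerateDataError):
            fit_feature_model([0.1, 0.2, 0.3, -0.9, np.nan, np.nan], design6)

    def test_matrix_fit_matches_row_fit(self, design6):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        X[rng.random(X.shape) < 0.15] = np.nan
        mat = pd.DataFrame(X, columns=design6.channels)
        fits, skipped = fit_all_features(mat, design6)
        for fid in fits.index:
            beta, s2, d = fit_feature_model(mat.loc[fid].to_numpy(), design6)
            assert fits.loc[fid, "log2fc"] == pytest.approx(beta)
            assert fits.loc[fid, "s2"] == pytest.approx(s2)
            assert fits.loc[fid, "df"] == d
        for fid in skipped:
            with pytest.raises(DegenerateDataError):
                fit_feature_model(mat.loc[fid].to_numpy(), design6)

    def test_weighted_fit_brackets_unweighted(self, design6):
        """With a 0.05-weighted outlier the effect lies between the
        all-equal-weights fit and the fit dropping it entirely."""
        vals = np.array([0.0, 0.1, -0.1, 1.0, 1.1, 3.0])
        w_soft = np.array([1, 1, 1, 1, 1, 0.05])
        b_all, _, _ = fit_feature_model(vals, design6)
        b_soft, _, _ = fit_feature_model(vals, design6, weights=w_soft)
        b_drop = np.mean([1.0, 1.1]) - np.mean([0.0, 0.1, -0.1])
        lo, hi = sorted([b_all, b_drop])
        assert lo <= b_soft <= hi


class TestPriorEstimation:
    def test_identical_variances_force_infinite_d0(self):
        prior = estimate_prior(np.full(20, 0.3), np.full(20, 4))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3 * 2 / math.exp(special.digamma(2)))

    def test_two_feature_hand_evaluation(self):
        """Direct numeric evaluation of the two moment equations for
        s2 = {1, e}, d = 4: the spread of e_g (0.5) does not exceed the
        sampling trigamma term psi'(2), so d0 is infinite and s0_sq is the
        bias-corrected geometric mean."""
        s2 = np.array([1.0, math.e])
        d = np.array([4, 4])
        e = np.log(s2) - special.digamma(2.0) + math.log(2.0)
        assert np.var(e, ddof=1) == pytest.approx(0.5)
        assert np.var(e, ddof=1) < special.polygamma(1, 2.0)
        prior = estimate_prior(s2, d)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(math.exp(float(np.mean(e))))

    def test_recovers_planted_hyperparameters(self):
        rng = np.random.default_rng(42)
        s2 = sample_variances(rng, n=5000, d=4, d0=4.0, s0_sq=1.0)
        prior = estimate_prior(s2, np.full(5000, 4))
        assert prior.d0 == pytest.approx(4.0, rel=0.2)
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(DegenerateDataError):
            estimate_prior(np.zeros(10), np.full(10, 4))

    def test_trigamma_inverse_round_trip(self):
        for x in (0.01, 0.5, 1.0, 2.0, 17.0, 300.0):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeration:
    def test_zero_d0_recovers_classical_t(self):
        rng = np.random.default_rng(3)
        c, t = rng.normal(size=3), rng.normal(size=3) + 1
        beta = t.mean() - c.mean()
        sp2 = (np.sum((c - c.mean()) ** 2) + np.sum((t - t.mean()) ** 2)) / 4
        t_mod, p, _ = moderate(beta, sp2, 4, ModerationPrior(1.0, 1.0), 2 / 3, d0_override=0.0)
        t_ref, p_ref, _ = pooled_t(c, t)
        assert t_mod[0] == pytest.approx(t_ref)
        assert p[0] == pytest.approx(p_ref)

    def test_infinite_d0_pins_posterior_to_prior(self):
        prior = ModerationPrior(math.inf, 0.7)
        _, _, s2_post = moderate(2.0, 5.0, 4, prior, 2 / 3)
        assert s2_post[0] == pytest.approx(0.7)

    def test_zero_effect_gives_p_one(self):
        t_mod, p, _ = moderate(0.0, 1.0, 4, ModerationPrior(4.0, 1.0), 2 / 3)
        assert t_mod[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(8)
        s2 = rng.chisquare(4, size=200) / 4
        prior = ModerationPrior(3.0, 1.2)
        _, _, s2_post = moderate(np.ones(200), s2, np.full(200, 4), prior, 2 / 3)
        lo = np.minimum(s2, prior.s0_sq)
        hi = np.maximum(s2, prior.s0_sq)
        assert np.all(s2_post >= lo - 1e-12)
        assert np.all(s2_post <= hi + 1e-12)

    def test_null_p_values_calibrated(self, design6):
        """Full moderated pipeline on pure-noise ratios: the fraction of
        p <= alpha should be within Monte-Carlo bounds of alpha."""
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(rng.normal(0, 0.3, size=(4000, 6)), columns=design6.channels)
        results, _ = run_differential(mat, design6)
        frac = float((results["p_value"] <= 0.05).mean())
        # 99.9% binomial band around 0.05 at n = 4000
        se = math.sqrt(0.05 * 0.95 / 4000)
        assert abs(frac - 0.05) < 3.3 * se


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_arithmetic_ladder_collapses_to_max(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(p), bh_step_up(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_and_dominates_p(self, p):
        q = adjust_bh(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCalls:
    def test_boundary_p_adj_is_significant(self):
        res = pd.DataFrame({"log2fc": [-1.0], "p_adj": [0.05]})
        out = call_significant(res)
        assert bool(out["significant"].iloc[0])
        assert out["direction"].iloc[0] == "down"

    def test_no_calls_above_alpha(self):
        res = pd.DataFrame({"log2fc": [1.0, -2.0], "p_adj": [0.06, 0.9]})
        assert not call_significant(res)["significant"].any()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaCrossCheck:
    """The in-package moderation against the reference empirical-Bayes
    implementation in Bioconductor's limma, on the same matrix."""

    def test_prior_and_moderated_p_match_limma(self, tmp_path, design6):
        rng = np.random.default_rng(2024)
        X = rng.normal(0, 0.4, size=(300, 6))
        X[:30, 3:] -= 1.0
        mat = pd.DataFrame(X, columns=design6.channels)
        mat.to_csv(tmp_path / "mat.tsv", sep="\t", index=False)
        rscript = """
        x <- as.matrix(read.delim('%s'))
        design <- cbind(Intercept=1, Treat=c(0,0,0,1,1,1))
        fit <- limma::eBayes(limma::lmFit(x, design))
        out <- data.frame(d0=fit$df.prior, s0=fit$s2.prior,
                          t=fit$t[, 'Treat'], p=fit$p.value[, 'Treat'])
        write.table(out, '%s', sep='\\t', row.names=FALSE)
        """ % (tmp_path / "mat.tsv", tmp_path / "limma.tsv")
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")

        results, prior = run_differential(mat, design6)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(results["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(results["p_value"], ref["p"], rtol=1e-8)
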