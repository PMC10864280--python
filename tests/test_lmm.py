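"""Zygosity-stratified mixed model: likelihood oracles, boundary behavior,
invariances, and the per-feature screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from cotwin.datasets import example_pair_counts, metadata_from_pair_counts
from cotwin.lmm import (TwinLMM, build_design, marginal_loglik, screen_features,
                        select_setup)


def random_twin_data(rng, n_pairs=10, p=2, sigma2=0.7, s2mz=0.5, s2dz=0.2,
                     singleton=False):
    """A small cohort plus its dense marginal covariance matrix."""
    pairs = np.repeat([f"p{j}" for j in range(n_pairs)], 2)
    zyg = np.repeat(rng.choice(["MZ", "DZ"], n_pairs), 2)
    if singleton:      # drop one member of the last pair
        pairs, zyg = pairs[:-1], zyg[:-1]
    n = len(pairs)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    beta = rng.standard_normal(p + 1)
    V = sigma2 * np.eye(n)
    for j in np.unique(pairs):
        idx = np.where(pairs == j)[0]
        tz = s2mz if zyg[idx[0]] == "MZ" else s2dz
        V[np.ix_(idx, idx)] += tz
    y = rng.multivariate_normal(X @ beta, V)
    return y, X, pairs, zyg, beta, V


class TestLikelihoodOracles:
    def test_block_loglik_matches_dense_mvn(self, rng):
        """Block eigen-rotation loglik == dense multivariate-normal density
        on 20 random cohorts of <= 40 individuals (some with a singleton)."""
        for k in range(20):
            n_pairs = int(rng.integers(4, 21))
            y, X, pairs, zyg, beta, V = random_twin_data(
                rng, n_pairs, singleton=(k % 3 == 0))
            ours = marginal_loglik(y, X, pairs, zyg, beta, 0.7, 0.5, 0.2)
            dense = stats.multivariate_normal(mean=X @ beta, cov=V).logpdf(y)
            assert ours == pytest.approx(dense, abs=1e-8)

    def test_shared_fit_matches_statsmodels_mixedlm(self, rng):
        """With one pair variance the model is an ordinary random-intercept
        LMM; the constrained fit reproduces the generic fitter's ML
        log-likelihood."""
        for k in range(3):
            y, X, pairs, zyg, _, _ = random_twin_data(
                rng, n_pairs=100, s2mz=0.4, s2dz=0.4)
            ours = TwinLMM(variance_structure="shared", fit_intercept=False)
            ours.fit(X, y, pairs=pairs, zygosity=zyg)
            generic = MixedLM(y, X, groups=pairs).fit(reml=False)
            assert ours.loglik_ == pytest.approx(generic.llf, abs=1e-6)
            np.testing.assert_allclose(ours.beta_.to_numpy(),
                                       generic.fe_params, atol=1e-5)

    def test_stratified_dominates_shared(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=80,
                                                  s2mz=0.8, s2dz=0.1)
        strat = TwinLMM(fit_intercept=False).fit(X, y, pairs=pairs, zygosity=zyg)
        shared = TwinLMM(variance_structure="shared", fit_intercept=False)
        shared.fit(X, y, pairs=pairs, zygosity=zyg)
        assert strat.loglik_ >= shared.loglik_ - 1e-9

    def test_optimum_beats_random_variance_points(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=60)
        m = TwinLMM(fit_intercept=False).fit(X, y, pairs=pairs, zygosity=zyg)
        at_opt = m.profiled_loglik(m.sigma2_, m.sigma2_mz_, m.sigma2_dz_)
        assert m.loglik_ == pytest.approx(at_opt, abs=1e-9)
        for _ in range(50):
            cand = np.exp(rng.normal(0.0, 1.5, 3))
            assert m.loglik_ >= m.profiled_loglik(*cand) - 1e-9

    def test_reml_pair_variance_matches_statsmodels(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=100,
                                                  s2mz=0.4, s2dz=0.4)
        ours = TwinLMM(variance_structure="shared", method="reml",
                       fit_intercept=False).fit(X, y, pairs=pairs, zygosity=zyg)
        generic = MixedLM(y, X, groups=pairs).fit(reml=True)
        pair_var = float(np.asarray(generic.cov_re)[0, 0])
        assert ours.sigma2_mz_ == pytest.approx(pair_var, rel=1e-3, abs=1e-6)
        assert ours.sigma2_ == pytest.approx(generic.scale, rel=1e-3)


class TestBoundaryAndInvariance:
    def test_zero_pair_variance_reduces_to_ols(self):
        """When the fitted pair variances hit the zero boundary the GLS
        estimate collapses to OLS (seed chosen so the boundary is hit)."""
        rng = np.random.default_rng(5)
        n_pairs = 80
        pairs = np.repeat([f"p{j}" for j in range(n_pairs)], 2)
        zyg = np.repeat(rng.choice(["MZ", "DZ"], n_pairs), 2)
        X = rng.standard_normal((2 * n_pairs, 2))
        y = 1.0 + X @ np.array([0.5, -0.3]) + rng.normal(0, 1, 2 * n_pairs)
        m = TwinLMM().fit(pd.DataFrame(X, columns=["a", "b"]), y,
                          pairs=pairs, zygosity=zyg)
        assert m.sigma2_mz_ < 1e-10 and m.sigma2_dz_ < 1e-10
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y,
                              rcond=None)[0]
        np.testing.assert_allclose(m.beta_.to_numpy(), ols, atol=1e-8)

    def test_estimates_invariant_to_reordering_and_relabeling(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=50)
        m1 = TwinLMM(fit_intercept=False).fit(X, y, pairs=pairs, zygosity=zyg)
        perm = rng.permutation(len(y))
        relabel = {p: f"q{k}" for k, p in enumerate(dict.fromkeys(pairs[perm]))}
        m2 = TwinLMM(fit_intercept=False).fit(
            X[perm], y[perm], pairs=np.array([relabel[p] for p in pairs[perm]]),
            zygosity=zyg[perm])
        np.testing.assert_allclose(m1.beta_.to_numpy(), m2.beta_.to_numpy(),
                                   atol=1e-8)
        assert m1.loglik_ == pytest.approx(m2.loglik_, abs=1e-8)

    def test_singular_design_names_collinear_column(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=20)
        Xdf = pd.DataFrame(X[:, 1:], columns=["a", "b"])
        Xdf["twice_a"] = 2 * Xdf["a"]
        with pytest.raises(ValueError, match="twice_a"):
            TwinLMM().fit(Xdf, y, pairs=pairs, zygosity=zyg)

    def test_pair_with_three_members_rejected(self, rng):
        y = rng.standard_normal(3)
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="more than 2"):
            TwinLMM(fit_intercept=False).fit(
                X, y, pairs=np.array(["p1"] * 3),
                zygosity=np.array(["MZ"] * 3))

    def test_sklearn_protocol(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=30)
        m = TwinLMM()
        assert m.get_params()["method"] == "ml"
        m.set_params(method="reml").fit(X[:, 1:], y, pairs=pairs, zygosity=zyg)
        assert hasattr(m, "beta_") and hasattr(m, "loglik_")
        pred = m.predict(X[:, 1:])
        assert pred.shape == y.shape

    def test_likelihood_ratio_test_agrees_with_wald_roughly(self, rng):
        y, X, pairs, zyg, _, _ = random_twin_data(rng, n_pairs=150)
        Xdf = pd.DataFrame(X[:, 1:], columns=["a", "b"])
        m = TwinLMM().fit(Xdf, y, pairs=pairs, zygosity=zyg)
        lr, p_lr = m.likelihood_ratio_test(Xdf, y, pairs, zyg, "a")
        assert lr >= 0
        p_wald = m.pvalues_["a"]
        assert np.sign(np.log(p_lr + 1e-300) - np.log(0.05)) == \
            np.sign(np.log(p_wald + 1e-300) - np.log(0.05)) or \
            abs(p_lr - p_wald) < 0.05


class TestScreen:
    def test_setup_sample_counts_on_reference_cohort(self, reference_metadata):
        idx_d = select_setup(reference_metadata, "d")
        meta_d = reference_metadata.loc[idx_d]
        assert len(meta_d) == 218
        assert int((meta_d["md"] == 0).sum()) == 74     # healthy co-twins
        assert int((meta_d["md"] == 1).sum()) == 144    # all MD twins
        idx_e = select_setup(reference_metadata, "e")
        meta_e = reference_metadata.loc[idx_e]
        assert len(meta_e) == 438
        assert int((meta_e["md"] == 0).sum()) == 294
        assert int((meta_e["md"] == 1).sum()) == 144

    def test_bh_adjustment_matches_step_up(self, small_cohort):
        from cotwin.preprocess import clr_transform
        clr = clr_transform(small_cohort.counts)
        res = screen_features(clr, small_cohort.metadata, setup="e",
                              covariates=("age", "sex"))
        p = res["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepup = np.empty(m)
        running = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            k = m - rank_from_top
            running = min(running, p[i] * m / k)
            stepup[i] = running
        np.testing.assert_allclose(res["q"].to_numpy(), stepup, atol=1e-12)

    def test_spiked_genus_detected_with_correct_sign(self, default_cohort):
        from cotwin.preprocess import clr_transform
        clr = clr_transform(default_cohort.counts)
        res = screen_features(clr, default_cohort.metadata, setup="d")
        for genus, eff in default_cohort.truth.affected_genera.items():
            assert res.loc[genus, "significant"]
            assert np.sign(res.loc[genus, "beta_md"]) == np.sign(eff)

    def test_constant_feature_skipped(self, small_cohort):
        feats = pd.DataFrame(
            {"flat": 1.0, "ok": np.arange(len(small_cohort.metadata), dtype=float)},
            index=small_cohort.metadata.index)
        res = screen_features(feats, small_cohort.metadata, setup="e",
                              covariates=())
        assert "flat" not in res.index and "ok" in res.index

    def test_covariate_switch_excluding_bmi(self, small_cohort):
        from cotwin.preprocess import clr_transform
        clr = clr_transform(small_cohort.counts)
        covs = ("age", "sex", "antibiotics", "veg", "fruit")
        res = screen_features(clr, small_cohort.metadata, setup="d",
                              covariates=covs)
        assert len(res) == clr.shape[1]
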