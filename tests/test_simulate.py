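"""Generator: liability-threshold phenotypes, pair-correlated features,
ground truth, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cotwin import (SimConfig, clr_transform, make_ground_truth,
                    simulate_cohort, simulate_confounders, simulate_counts,
                    simulate_metabolites, simulate_pathways,
                    simulate_phenotypes)


def quadrature_concordance(r: float, prevalence: float) -> float:
    """Independent oracle: proband-wise concordance P(L2>t | L1>t) for a
    bivariate standard normal with correlation r, by Gauss-Legendre
    quadrature of P(both>t) = int_t^inf phi(x) * Phibar((t-r x)/sqrt(1-r^2)) dx."""
    t = stats.norm.ppf(1 - prevalence)
    nodes, weights = np.polynomial.legendre.leggauss(200)
    lo, hi = t, t + 12.0
    x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * weights
    upper_tail = stats.norm.sf((t - r * x) / np.sqrt(1 - r ** 2))
    p_both = float(np.sum(w * stats.norm.pdf(x) * upper_tail))
    return p_both / prevalence


def empirical_concordance(meta: pd.DataFrame, zygosity: str) -> float:
    sub = meta[meta["zygosity"] == zygosity]
    by_pair = sub.groupby("pair_id")["md"].sum()
    C = int((by_pair == 2).sum())
    D = int((by_pair == 1).sum())
    return 2 * C / (2 * C + D)


class TestPhenotypes:
    def test_concordance_matches_quadrature_oracle(self):
        cfg = SimConfig(n_mz_pairs=5000, n_dz_pairs=5000, prevalence=0.33,
                        liability_corr_mz=0.8, liability_corr_dz=0.4, seed=5)
        meta = simulate_phenotypes(cfg)
        for zyg, r in (("MZ", 0.8), ("DZ", 0.4)):
            expected = quadrature_concordance(r, 0.33)
            observed = empirical_concordance(meta, zyg)
            # binomial SE on ~5000*2*prev probands
            se = np.sqrt(expected * (1 - expected) / (2 * 5000 * 0.33))
            assert abs(observed - expected) < 4 * se
        assert empirical_concordance(meta, "MZ") > empirical_concordance(meta, "DZ")

    def test_perfect_correlation_gives_full_concordance(self):
        cfg = SimConfig(n_mz_pairs=800, n_dz_pairs=1, prevalence=0.3,
                        liability_corr_mz=1.0, seed=2)
        meta = simulate_phenotypes(cfg)
        mz = meta[meta["zygosity"] == "MZ"]
        by_pair = mz.groupby("pair_id")["md"].sum()
        assert not (by_pair == 1).any()  # no discordant pairs at r=1
        assert empirical_concordance(meta, "MZ") == 1.0

    def test_zero_correlation_concordance_equals_prevalence(self):
        cfg = SimConfig(n_mz_pairs=20000, n_dz_pairs=1, prevalence=0.3,
                        liability_corr_mz=0.0, seed=3)
        meta = simulate_phenotypes(cfg)
        assert empirical_concordance(meta, "MZ") == pytest.approx(0.3, abs=0.02)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(liability_corr_mz=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(liability_corr_dz=-0.2).validate()


class TestCounts:
    def test_rows_sum_to_depth_and_are_integral(self, small_cohort):
        counts = small_cohort.counts
        assert (counts.sum(axis=1) == small_cohort.config.seq_depth).all()
        assert (counts.to_numpy() >= 0).all()
        assert counts.to_numpy().dtype.kind in "iu"

    def test_zero_variance_no_effect_gives_constant_composition(self):
        cfg = SimConfig(n_mz_pairs=10, n_dz_pairs=10, n_genera=6,
                        n_affected_genera=0, effect_size_genus=0.0,
                        pair_var_mz=0.0, pair_var_dz=0.0, residual_var=0.0,
                        n_metabolites=2, n_affected_metabolites=0,
                        n_pathways=2, seq_depth=200000, seed=4)
        c = simulate_cohort(cfg)
        rel = c.counts.div(c.counts.sum(axis=1), axis=0)
        # identical expected composition for every sample: only multinomial
        # noise remains at large depth
        assert (rel.std(axis=0) < 0.005).all()

    def test_spiked_genus_shifts_clr(self):
        cfg = SimConfig(n_mz_pairs=500, n_dz_pairs=500, n_affected_genera=1,
                        effect_size_genus=1.0, n_metabolites=2,
                        n_affected_metabolites=0, n_pathways=2, seed=6)
        c = simulate_cohort(cfg)
        genus, eff = next(iter(c.truth.affected_genera.items()))
        assert eff > 0
        clr = clr_transform(c.counts)
        md = c.metadata["md"].astype(bool)
        assert clr.loc[md, genus].mean() > clr.loc[~md, genus].mean() + 0.3

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seq_depth=0).validate()


class TestMetabolitesAndConfounders:
    def test_no_missingness_when_rate_zero(self):
        cfg = SimConfig(n_mz_pairs=20, n_dz_pairs=20, n_metabolites=8,
                        missing_rate_metabolite=0.0, n_genera=4,
                        n_affected_genera=1, n_pathways=2, seed=7)
        c = simulate_cohort(cfg)
        assert not c.metabolites.isna().any().any()

    def test_missing_rate_realized(self):
        cfg = SimConfig(n_mz_pairs=60, n_dz_pairs=50, n_metabolites=20,
                        missing_rate_metabolite=0.3, n_genera=4,
                        n_affected_genera=1, n_pathways=2, seed=8)
        c = simulate_cohort(cfg)
        frac = float(c.metabolites.isna().to_numpy().mean())
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_bmi_correlated_within_pairs(self):
        cfg = SimConfig(n_mz_pairs=1500, n_dz_pairs=1500, n_genera=2,
                        n_affected_genera=0, n_metabolites=2,
                        n_affected_metabolites=0, n_pathways=2, seed=9)
        meta = simulate_confounders(cfg, simulate_phenotypes(cfg))
        wide = meta.reset_index().assign(
            member=lambda d: d["sample_id"].str[-1]).pivot(
            index="pair_id", columns="member", values="bmi")
        r = np.corrcoef(wide["1"], wide["2"])[0, 1]
        assert r > 0.3
        # age and sex are fully pair-shared
        assert (meta.groupby("pair_id")["age"].nunique() == 1).all()
        assert (meta.groupby("pair_id")["sex"].nunique() == 1).all()

    def test_confounder_leakage_inflates_unadjusted_association(self):
        """With BMI->genus leakage and an MD->BMI shift, the unadjusted MD
        contrast on the leaky genus exceeds the BMI-adjusted one."""
        from cotwin.lmm import TwinLMM, build_design
        deltas_unadj, deltas_adj = [], []
        for rep in range(10):
            cfg = SimConfig(n_affected_genera=0, effect_size_genus=0.0,
                            n_metabolites=2, n_affected_metabolites=0,
                            n_pathways=2, confounder_leakage=1.5,
                            bmi_md_shift=4.0, seed=700 + rep)
            c = simulate_cohort(cfg)
            clr = clr_transform(c.counts)
            y = clr[clr.columns[0]].to_numpy()  # leakage targets genus 0
            meta = c.metadata
            for covs, bucket in ((('age',), deltas_unadj),
                                 (("age", "bmi"), deltas_adj)):
                m = TwinLMM().fit(build_design(meta, covs), y,
                                  pairs=meta["pair_id"].to_numpy(),
                                  zygosity=meta["zygosity"].to_numpy())
                bucket.append(abs(m.beta_["md"] / m.bse_["md"]))
        assert np.mean(deltas_unadj) > np.mean(deltas_adj)


class TestPathways:
    def test_identity_loading_zero_noise_reproduces_clr(self, rng):
        cfg = SimConfig(n_mz_pairs=10, n_dz_pairs=10, n_genera=5,
                        n_pathways=5, n_affected_genera=1, n_metabolites=2,
                        n_affected_metabolites=0, seed=10)
        truth = make_ground_truth(cfg)
        truth.pathway_loadings.iloc[:, :] = np.eye(5)
        meta = simulate_phenotypes(cfg)
        counts = simulate_counts(cfg, meta, truth)
        pathw = simulate_pathways(counts, truth, noise_sd=0.0)
        clr = clr_transform(counts)
        for k in range(5):
            rho = stats.spearmanr(clr.iloc[:, k], pathw.iloc[:, k]).statistic
            assert rho == pytest.approx(1.0)

    def test_unknown_genus_in_loadings_rejected(self, small_cohort):
        truth = small_cohort.truth
        bad = truth.pathway_loadings.copy()
        bad.columns = [f"zz{i}" for i in range(bad.shape[1])]
        from cotwin.simulate import GroundTruth
        with pytest.raises(ValueError):
            simulate_pathways(small_cohort.counts,
                              GroundTruth({}, {}, bad))


class TestDeterminismAndIO:
    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig(n_mz_pairs=8, n_dz_pairs=8, n_genera=6,
                        n_metabolites=5, n_pathways=4, seed=13)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.pathways, b.pathways)

    def test_roundtrip_through_tsv(self, small_cohort, tmp_path):
        small_cohort.to_dir(tmp_path)
        back = type(small_cohort).from_dir(tmp_path)
        pd.testing.assert_frame_equal(back.counts, small_cohort.counts)
        np.testing.assert_allclose(back.metabolites.to_numpy(),
                                   small_cohort.metabolites.to_numpy())
        assert back.truth.affected_genera == small_cohort.truth.affected_genera
        pd.testing.assert_frame_equal(back.truth.pathway_loadings,
                                      small_cohort.truth.pathway_loadings)
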