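"""Generative correctness of the trio simulator: Hardy-Weinberg,
Balding-Nichols differentiation, copula LD, Mendelian transmission,
assortative pairing, and phenotype calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomr import (SimConfig, assortative_pairing, inject_outliers_and_missingness,
                    simulate_cohort, simulate_founders, transmit_genotypes)
from triomr.config import ConfigError


class TestFounders:
    def test_hardy_weinberg_at_known_maf(self):
        cfg = SimConfig(n_families=4000, n_snps=40, maf_range=(0.5, 0.5),
                        fst=0.0, n_subpops=1, ld_rho=0.0, seed=1)
        founders = simulate_founders(cfg)
        freqs = founders.allele_freqs()
        assert np.allclose(freqs, 0.5, atol=0.02)
        # genotype variance 2 p (1-p) = 0.5 at p = 0.5
        var = founders.dosages.astype(float).var(axis=0)
        assert np.allclose(var, 0.5, atol=0.03)

    def test_balding_nichols_between_subpop_variance(self):
        """Per-subpop allele frequencies spread like the Beta(p(1-F)/F, ...)
        draw; the Monte-Carlo oracle is a direct Beta simulation."""
        fst, p = 0.1, 0.3
        cfg = SimConfig(n_families=3000, n_snps=300, maf_range=(p, p),
                        fst=fst, n_subpops=2, seed=3)
        founders = simulate_founders(cfg)
        diffs = []
        for s in (0, 1):
            rows = founders.subpop == s
            diffs.append(founders.dosages[rows].mean(axis=0) / 2.0)
        observed = np.mean(np.abs(diffs[0] - diffs[1]))
        # oracle: |p1 - p2| for independent Balding-Nichols draws
        rng = np.random.default_rng(0)
        a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
        draws = rng.beta(a, b, size=(200000, 2))
        expected = np.abs(draws[:, 0] - draws[:, 1]).mean()
        assert observed == pytest.approx(expected, rel=0.1)
        # variance of the Beta is F p (1 - p)
        assert draws.var() == pytest.approx(fst * p * (1 - p), rel=0.05)

    def test_ld_matches_bruteforce_copula_oracle(self):
        """Adjacent-SNP dosage correlation equals a direct simulation of the
        thresholded AR(1) copula at the same MAF."""
        rho, p = 0.9, 0.3
        cfg = SimConfig(n_families=6000, n_snps=10, ld_block_size=10,
                        ld_rho=rho, maf_range=(p, p), fst=0.0, seed=5)
        founders = simulate_founders(cfg)
        d = founders.dosages.astype(float)
        obs = np.mean([np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(9)])
        # brute-force oracle: two correlated latents per haplotype, thresholded
        rng = np.random.default_rng(11)
        t = stats.norm.ppf(p)
        z1 = rng.standard_normal((400000, 2))
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((400000, 2))
        dos1 = (z1 < t).sum(axis=1)
        dos2 = (z2 < t).sum(axis=1)
        expected = np.corrcoef(dos1, dos2)[0, 1]
        assert obs == pytest.approx(expected, abs=0.03)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="fst"):
            SimConfig(fst=0.7)
        with pytest.raises(ConfigError, match="maf_range"):
            SimConfig(maf_range=(0.0, 0.5))


class TestTransmission:
    def test_fixation(self):
        rng = np.random.default_rng(0)
        two = np.full((1, 50), 2)
        zero = np.zeros((1, 50), dtype=int)
        assert (transmit_genotypes(two, two, rng) == 2).all()
        assert (transmit_genotypes(zero, zero, rng) == 0).all()

    def test_het_cross_distribution_matches_enumeration(self):
        """1 x 1 cross gives {0: 1/4, 1: 1/2, 2: 1/4} (four equally likely
        allele draws)."""
        rng = np.random.default_rng(1)
        ones = np.ones((20000, 1), dtype=int)
        kids = transmit_genotypes(ones, ones, rng).ravel()
        freq = np.bincount(kids, minlength=3) / len(kids)
        # enumeration oracle over the four transmissions
        combos = [(a + b) for a in (0, 1) for b in (0, 1)]
        expected = np.bincount(combos) / 4.0
        assert np.allclose(freq, expected, atol=0.02)

    def test_mendelian_consistency_bounds(self):
        rng = np.random.default_rng(2)
        dm = rng.integers(0, 3, size=(500, 30))
        df = rng.integers(0, 3, size=(500, 30))
        kid = transmit_genotypes(dm, df, rng)
        assert (kid >= (dm > 1).astype(int) + (df > 1).astype(int)).all()
        assert (kid <= (dm > 0).astype(int) + (df > 0).astype(int)).all()

    def test_rejects_fractional_dosages(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="hard calls"):
            transmit_genotypes(np.array([[0.5]]), np.array([[1.0]]), rng)


class TestAssortativePairing:
    def test_random_pairing_null_correlation(self):
        rng = np.random.default_rng(0)
        n = 4000
        m = pd.DataFrame({"bmi": rng.standard_normal(n)})
        f = pd.DataFrame({"bmi": rng.standard_normal(n)})
        perm = assortative_pairing(m, f, 0.0, rng)
        r = np.corrcoef(m["bmi"], f["bmi"].to_numpy()[perm])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_perfect_target_equals_sort_oracle(self):
        rng = np.random.default_rng(1)
        n = 1000
        m = pd.DataFrame({"bmi": rng.standard_normal(n)})
        f = pd.DataFrame({"bmi": rng.standard_normal(n)})
        perm = assortative_pairing(m, f, 1.0, rng)
        # oracle: sort both sides and pair by rank
        expected = np.corrcoef(np.sort(m["bmi"]), np.sort(f["bmi"]))[0, 1]
        realized = np.corrcoef(m["bmi"], f["bmi"].to_numpy()[perm])[0, 1]
        assert realized == pytest.approx(expected, abs=1e-12)

    def test_moderate_target_realized(self):
        rng = np.random.default_rng(2)
        n = 20000
        m = pd.DataFrame({"bmi": rng.standard_normal(n)})
        f = pd.DataFrame({"bmi": rng.standard_normal(n)})
        perm = assortative_pairing(m, f, 0.23, rng)
        r = np.corrcoef(m["bmi"], f["bmi"].to_numpy()[perm])[0, 1]
        assert r == pytest.approx(0.23, abs=0.02)

    def test_infeasible_target_raises(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"bmi": rng.standard_normal(100)})
        f = pd.DataFrame({"bmi": rng.standard_normal(100)})
        with pytest.raises(ValueError, match="exceeds 1"):
            assortative_pairing(m, f, 1.5, rng)

    def test_non_rank_one_target_raises(self):
        rng = np.random.default_rng(4)
        n = 200
        m = pd.DataFrame({"bmi": rng.standard_normal(n), "symptoms": rng.standard_normal(n)})
        f = pd.DataFrame({"bmi": rng.standard_normal(n), "symptoms": rng.standard_normal(n)})
        targets = {("bmi", "bmi"): 0.5, ("symptoms", "symptoms"): 0.5,
                   ("bmi", "symptoms"): 0.0}
        with pytest.raises(ValueError, match="rank-1"):
            assortative_pairing(m, f, targets, rng)


class TestPhenotypes:
    def test_parent_child_score_correlation_is_half(self, null_cohort):
        df = null_cohort.df
        for parent in ("g_mother", "g_father"):
            r = np.corrcoef(df["g_child"], df[parent])[0, 1]
            assert r == pytest.approx(0.5, abs=3 / np.sqrt(len(df)))

    def test_child_score_variance_equilibrium(self, null_cohort):
        df = null_cohort.df
        assert df["g_child"].var() == pytest.approx(
            0.5 * (df["g_mother"].var() + df["g_father"].var()) / 2 + 0.5, rel=0.05)

    def test_pgs_r2_calibration(self):
        df = simulate_cohort(SimConfig(n_families=40000, n_snps=0, seed=9)).df
        for role, target in (("child", 0.017), ("mother", 0.032), ("father", 0.030)):
            r2 = np.corrcoef(df[f"g_{role}"], df[f"{role}_bmi"])[0, 1] ** 2
            assert r2 == pytest.approx(target, abs=0.004)

    def test_bmi_moments_match_cohort_description(self):
        df = simulate_cohort(SimConfig(n_families=40000, n_snps=0, seed=10)).df
        for role, mean, sd in (("child", 16.3, 2.0), ("mother", 24.0, 4.1),
                               ("father", 25.9, 3.2)):
            assert df[f"{role}_bmi"].mean() == pytest.approx(mean, abs=0.05)
            assert df[f"{role}_bmi"].std() == pytest.approx(sd, rel=0.02)

    def test_null_outcome_unit_variance_and_no_bmi_effect(self, null_cohort):
        df = null_cohort.df
        assert df["y_symptoms"].var() == pytest.approx(1.0, rel=0.03)
        slope = np.polyfit(df["child_bmi"] / 5, df["y_symptoms"], 1)[0]
        assert abs(slope) < 3 * 1.0 / (np.sqrt(len(df)) * df["child_bmi"].std() / 5)

    def test_confounding_bias_matches_omitted_variable_formula(self):
        """OLS of outcome on child BMI under confounding equals
        beta + c_out * cov(x, C) / var(x) (closed form)."""
        from dataclasses import replace
        cfg = replace(SimConfig.global_null(n_families=150000, seed=12),
                      beta_child=0.3, confounder_sd=0.3)
        df = simulate_cohort(cfg).df
        x = (df["child_bmi"] / 5).to_numpy()
        y = df["y_symptoms"].to_numpy()
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        c = 0.3
        sd_c = 2.0
        # cov(x, C) = sd_c * c / 5 ; var(x) = (sd_c / 5)^2
        expected = 0.3 + c * (sd_c * c / 5) / (sd_c / 5) ** 2
        assert slope == pytest.approx(expected, abs=0.03)

    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(n_families=300, n_snps=60, seed=21, sibship_rate=0.2)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert a.df.to_csv() == b.df.to_csv()
        assert (a.genotypes["child"].dosages == b.genotypes["child"].dosages).all()

    def test_sibships_share_cluster_and_parents(self):
        cfg = SimConfig(n_families=400, n_snps=0, seed=4, sibship_rate=0.25)
        df = simulate_cohort(cfg).df
        assert len(df) == 500
        assert df["family_id"].is_unique
        dup = df[df.duplicated("cluster_id", keep=False)]
        assert not dup.empty
        for _, grp in dup.groupby("cluster_id"):
            assert grp["mother_bmi"].nunique() == 1
            assert grp["father_bmi"].nunique() == 1
            assert grp["confounder"].nunique() == 1

    def test_child_dosage_mendelian_consistent(self, snp_cohort):
        g = snp_cohort.genotypes
        kid, mom, dad = (g[r].dosages for r in ("child", "mother", "father"))
        assert (kid >= (mom > 1).astype(int) + (dad > 1).astype(int)).all()
        assert (kid <= (mom > 0).astype(int) + (dad > 0).astype(int)).all()

    def test_ordinal_items_track_liability(self, snp_cohort):
        items = snp_cohort.items["smfq"]
        assert items.shape[1] == 13
        assert items.to_numpy().max() <= 2
        total = items.sum(axis=1)
        r = np.corrcoef(total, snp_cohort.df["y_smfq"])[0, 1]
        assert r > 0.4


class TestCorruption:
    def test_zero_rates_identity(self, snp_cohort):
        corrupted, log = inject_outliers_and_missingness(snp_cohort, 0.0, 0.0)
        pd.testing.assert_frame_equal(corrupted.df, snp_cohort.df)
        assert log.empty

    def test_outliers_flagged_by_4sd_rule(self):
        from triomr import clean_anthropometrics
        cfg = SimConfig(n_families=10000, n_snps=0, seed=8)
        cohort = simulate_cohort(cfg)
        corrupted, log = inject_outliers_and_missingness(
            cohort, outlier_rate=0.01, missing_rate=0.0,
            columns=("child_weight",), magnitude_sd=10.0, seed=1)
        n_out = (log["kind"] == "outlier").sum()
        assert n_out == 100
        cleaned = clean_anthropometrics(corrupted.df["child_height"],
                                        corrupted.df["child_weight"])
        flagged = cleaned["weight"].isna()
        assert flagged[log.loc[log.kind == "outlier", "row"]].all()

    def test_missing_rate_realized(self, snp_cohort):
        corrupted, log = inject_outliers_and_missingness(
            snp_cohort, 0.0, 0.3, columns=("child_weight",), seed=2)
        frac = corrupted.df["child_weight"].isna().mean()
        assert frac == pytest.approx(0.3, abs=0.01)
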