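"""Summary-statistic MR estimators: closed-form oracles, robustness
properties, SNP-outcome associations with parental adjustment, and
spousal assortment diagnostics."""

import numpy as np
import pandas as pd
import pytest

from triomr import (SimConfig, assortment_diagnostics, egger, harmonize, ivw,
                    mode_based, simulate_cohort, snp_outcome_assoc,
                    weighted_median)
from triomr.sensitivity import _wls, cochran_q
from triomr.simulate import transmit_genotypes

from conftest import make_geno


def summaries(beta_exp, beta_out, se_out, se_exp=None):
    k = len(beta_exp)
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(k)],
        "beta_exp": beta_exp, "se_exp": se_exp or [0.01] * k,
        "beta_out": beta_out, "se_out": se_out,
    })


def simulate_summary_mr(n=30000, m=50, beta=0.3, pleio_mean=0.0, pleio_sd=0.0,
                        invalid_frac=0.0, invalid_shift=0.0, seed=0,
                        se_gwas=0.002, b_range=(0.05, 0.15)):
    """Individual-level generative model for summary-statistic MR.

    Unrelated individuals; exposure x = sum b_j g_j + e; outcome
    y = beta x + sum theta_j g_j + eps with per-SNP direct effects theta_j
    independent of instrument strength (InSIDE).  Per-SNP associations are
    marginal regressions (valid because SNPs are simulated independent).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.5, size=m)
    g = rng.binomial(2, p, size=(n, m)).astype(float)
    # ascending instrument strength: the invalid minority (first indices)
    # sits on the weakest instruments, so under inverse-variance ratio
    # weights the valid SNPs keep more than half the total weight
    b = np.sort(rng.uniform(*b_range, size=m))
    theta = rng.normal(pleio_mean, pleio_sd, size=m) if (pleio_mean or pleio_sd) else np.zeros(m)
    n_invalid = int(round(invalid_frac * m))
    theta[:n_invalid] += invalid_shift
    x = g @ b + rng.standard_normal(n) * 2.0
    y = beta * x + g @ theta + rng.standard_normal(n) * 2.0
    gc = g - g.mean(axis=0)
    var_g = (gc**2).mean(axis=0)
    beta_out = (gc * y[:, None]).mean(axis=0) / var_g
    resid_var = np.array([np.var(y - beta_out[j] * gc[:, j]) for j in range(m)])
    se_out = np.sqrt(resid_var / (n * var_g))
    beta_exp = b + rng.normal(0, se_gwas, size=m)  # external GWAS estimate
    return summaries(beta_exp, beta_out, se_out, se_exp=[se_gwas] * m)


class TestIVW:
    def test_worked_two_snp_fixed_effect(self):
        s = summaries([1.0, 1.0], [0.5, 1.0], [0.1, 0.2])
        r = ivw(s, random_effects=False)
        assert r.beta == pytest.approx(0.6)
        assert r.se == pytest.approx(1 / np.sqrt(125))

    def test_exact_proportionality_zero_heterogeneity(self):
        s = summaries([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], [0.01, 0.01, 0.01])
        r = ivw(s)
        assert r.beta == pytest.approx(0.3)
        assert cochran_q(s)["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_recovers_truth_under_balanced_pleiotropy(self):
        s = simulate_summary_mr(beta=0.3, pleio_mean=0.0, pleio_sd=0.01, seed=1)
        r = ivw(s)
        assert r.beta == pytest.approx(0.3, abs=3 * max(r.se, 0.02))

    def test_requires_two_snps(self):
        with pytest.raises(ValueError, match="at least 2"):
            ivw(summaries([1.0], [0.5], [0.1]))

    def test_matches_2sls_wald_on_single_instrument_cohort(self):
        """IVW on one strong instrument's summary pair agrees with the
        individual-level Wald ratio (first-order asymptotics)."""
        from triomr import classic_mr
        df = simulate_cohort(SimConfig.global_null(n_families=40000, seed=9)).df
        rec = classic_mr(df, "y_symptoms", covariates=(), cluster=None,
                         transform="none")
        # summary-level: regress exposure and outcome on the instrument
        z = df["pgs_child"].to_numpy()
        zc = z - z.mean()
        bx = zc @ (df["child_bmi"] / 5) / (zc @ zc)
        by = zc @ df["y_symptoms"] / (zc @ zc)
        wald = by / bx
        assert rec.beta == pytest.approx(wald, rel=1e-6)


class TestEgger:
    def test_three_snp_closed_form(self):
        s = summaries([0.1, 0.2, 0.3], [0.05, 0.08, 0.07], [0.02, 0.03, 0.025])
        out = egger(s)
        w = 1 / np.array([0.02, 0.03, 0.025]) ** 2
        X = np.column_stack([np.ones(3), [0.1, 0.2, 0.3]])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * np.array([0.05, 0.08, 0.07])))
        assert out["intercept"].beta == pytest.approx(coef[0], rel=1e-9)
        assert out["slope"].beta == pytest.approx(coef[1], rel=1e-9)

    def test_reduces_to_ivw_without_intercept(self):
        s = simulate_summary_mr(seed=2, m=20)
        df = harmonize(s)
        w = 1 / df["se_out"].to_numpy() ** 2
        coef, _, _ = _wls(df["beta_exp"].to_numpy(), df["beta_out"].to_numpy(),
                          w, intercept=False)
        assert ivw(s).beta == pytest.approx(coef[0], rel=1e-12)

    def test_no_pleiotropy_null_intercept(self):
        s = simulate_summary_mr(beta=0.3, seed=3)
        out = egger(s)
        assert abs(out["intercept"].beta) < 3 * out["intercept"].se

    def test_directional_pleiotropy_recovered(self):
        s = simulate_summary_mr(beta=0.3, pleio_mean=0.02, pleio_sd=0.005, seed=4)
        out = egger(s)
        assert out["intercept"].beta == pytest.approx(0.02, abs=3 * out["intercept"].se)
        assert out["slope"].beta == pytest.approx(0.3, abs=3 * out["slope"].se)

    def test_orientation_violation_rejected(self):
        s = summaries([-0.1, 0.2, 0.3], [0.05, 0.08, 0.07], [0.02, 0.03, 0.025])
        with pytest.raises(ValueError, match="oriented positive"):
            egger(s)


class TestWeightedMedian:
    def test_equal_weights_unweighted_median(self):
        s = summaries([1.0] * 3, [0.2, 0.5, 0.9], [1.0] * 3)
        assert weighted_median(s, n_boot=50).beta == pytest.approx(0.5)

    def test_breakdown_under_49_percent_invalid(self):
        # strong instruments keep per-SNP ratio noise well below the
        # pleiotropic shift so the invalid minority is separable
        s = simulate_summary_mr(n=100000, beta=0.3, invalid_frac=0.49,
                                invalid_shift=0.15, m=60, seed=5,
                                b_range=(0.3, 0.5))
        r = weighted_median(s, n_boot=200, seed=1)
        naive = ivw(s)
        assert abs(r.beta - 0.3) < abs(naive.beta - 0.3)
        assert r.beta == pytest.approx(0.3, abs=0.05)

    def test_degenerate_weights_pick_dominant_snp(self):
        s = summaries([1.0] * 3, [0.2, 0.5, 0.9], [1e-4, 1.0, 1.0])
        assert weighted_median(s, n_boot=50).beta == pytest.approx(0.2, abs=0.01)

    def test_order_and_zero_weight_invariance(self):
        s = simulate_summary_mr(seed=6, m=12)
        a = weighted_median(s, n_boot=100, seed=3).beta
        b = weighted_median(s.iloc[::-1].reset_index(drop=True), n_boot=100, seed=3).beta
        assert a == pytest.approx(b, rel=1e-9)
        dup = pd.concat([s, s.iloc[[0]].assign(se_out=1e6)], ignore_index=True)
        c = weighted_median(dup, n_boot=100, seed=3).beta
        assert c == pytest.approx(a, abs=1e-6)


class TestModeBased:
    def test_identical_ratios_exact(self):
        s = summaries([1.0] * 3, [0.3] * 3, [0.1, 0.2, 0.1])
        r = mode_based(s, n_boot=10)
        assert r.beta == pytest.approx(0.3)

    def test_majority_cluster_wins(self):
        ratios = [0.29, 0.3, 0.31, 0.3, 0.295, 0.305, 0.3, 1.0, 1.02, 0.98]
        s = summaries([1.0] * 10, ratios, [0.05] * 10)
        assert mode_based(s, n_boot=50).beta == pytest.approx(0.3, abs=0.05)

    def test_infinite_bandwidth_limit_is_weighted_mean(self):
        s = summaries([1.0] * 4, [0.1, 0.2, 0.4, 0.9], [0.1, 0.2, 0.1, 0.3])
        w = 1 / (np.array([0.1, 0.2, 0.1, 0.3])) ** 2
        expected = np.average([0.1, 0.2, 0.4, 0.9], weights=w)
        r = mode_based(s, bandwidth_factor=500.0, n_boot=10)
        assert r.beta == pytest.approx(expected, abs=0.02)

    def test_invalid_bandwidth_rejected(self):
        s = summaries([1.0] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(ValueError, match="bandwidth"):
            mode_based(s, bandwidth_factor=0.0)


class TestSnpOutcomeAssoc:
    def test_direct_effect_recovered(self):
        rng = np.random.default_rng(0)
        n = 8000
        g = rng.binomial(2, 0.3, size=(n, 2)).astype(np.int8)
        y = 0.1 * g[:, 0] + rng.standard_normal(n)
        geno = make_geno(g)
        out = snp_outcome_assoc(geno, y)
        r0 = out.set_index("snp_id").loc["rs0"]
        assert r0["beta_out"] == pytest.approx(0.1, abs=3 * r0["se_out"])

    def test_dynastic_snp_killed_by_parental_adjustment(self):
        """A SNP acting only through the mother's genotype associates with
        the child outcome marginally but not once parental dosage is
        conditioned on (transmission logic)."""
        rng = np.random.default_rng(1)
        n = 20000
        gm = rng.binomial(2, 0.4, size=(n, 1))
        gf = rng.binomial(2, 0.4, size=(n, 1))
        gc = transmit_genotypes(gm, gf, rng)
        y = 0.15 * gm[:, 0] + rng.standard_normal(n)
        child, mother, father = (make_geno(x) for x in (gc, gm, gf))
        raw = snp_outcome_assoc(child, y).iloc[0]
        adj = snp_outcome_assoc(child, y, mother=mother, father=father,
                                adjust_parental=True).iloc[0]
        assert raw["beta_out"] > 3 * raw["se_out"]
        assert abs(adj["beta_out"]) < 3 * adj["se_out"]
        assert abs(adj["beta_out"]) < raw["beta_out"] / 3

    def test_null_snp_type_one_error(self):
        rng = np.random.default_rng(2)
        n, m = 2000, 60
        g = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        y = rng.standard_normal(n)
        out = snp_outcome_assoc(make_geno(g), y)
        z = (out["beta_out"] / out["se_out"]).abs()
        assert (z < 1.96).mean() > 0.85

    def test_monomorphic_snp_skipped(self):
        g = np.column_stack([np.full(100, 2, dtype=np.int8),
                             np.random.default_rng(3).binomial(2, 0.5, 100)])
        out = snp_outcome_assoc(make_geno(g), np.random.default_rng(4).standard_normal(100))
        assert out["snp_id"].tolist() == ["rs1"]


class TestAssortmentDiagnostics:
    def test_spousal_bmi_coefficient(self):
        df = simulate_cohort(SimConfig(n_families=40949, n_snps=0, seed=31)).df
        grid = assortment_diagnostics(df)
        row = grid.set_index(["father_trait", "mother_trait"]).loc[
            ("father_bmi", "mother_bmi")]
        assert row["beta"] == pytest.approx(0.23, abs=0.02)

    def test_random_mating_null_grid(self):
        df = simulate_cohort(SimConfig.global_null(n_families=20000, seed=32)).df
        grid = assortment_diagnostics(df)
        assert (grid["beta"].abs() < 3 * grid["se"]).all()

    def test_cross_trait_assortment_recovered(self):
        targets = {("bmi", "bmi"): 0.2, ("bmi", "symptoms"): 0.1}
        from dataclasses import replace
        cfg = replace(SimConfig.global_null(n_families=30000, seed=33),
                      spousal_corr=targets)
        df = simulate_cohort(cfg).df
        grid = assortment_diagnostics(df).set_index(["father_trait", "mother_trait"])
        assert grid.loc[("father_bmi", "mother_bmi"), "beta"] == pytest.approx(0.2, abs=0.02)
        assert grid.loc[("father_sym", "mother_bmi"), "beta"] == pytest.approx(0.1, abs=0.02)

    def test_unbalanced_input_rejected(self):
        df = simulate_cohort(SimConfig.global_null(n_families=200, seed=34)).df
        with pytest.raises(ValueError, match="father trait"):
            assortment_diagnostics(df, father_traits=("nonexistent",))
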