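"""Forward simulation of mother-father-child trio cohorts.

Generates SNP dosage genotypes for founder couples under a
Balding–Nichols subpopulation model with optional within-block LD
(Gaussian copula, AR(1) latent correlation), pairs spouses by
Gaussian-copula rank matching on latent mating scores (assortative
mating), transmits alleles to children by per-SNP Mendelian draws, and
builds phenotypes:

    BMI_i     = mean_i + sd_i * ( sqrt(r2_i) G_i + shift_s + c C_fam + e_i )
    outcome   = beta_child BMI_c/5 + alpha_m BMI_m/5 + alpha_f BMI_f/5
                + theta G_c + shift'_s + c' C_fam + eps

with G_i the standardized true polygenic score, C_fam a family-level
confounder shared by all trio members, and shift_s per-subpopulation
mean shifts.  The outcome noise is scaled so the outcome has unit
variance under the null configuration.

A score-level fast path (``n_snps = 0``) draws the true scores directly
(parents standard normal, child = mid-parent + segregation noise of
variance 1/2), which is exact for everything downstream that does not
touch individual SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, ConfigError, OutcomeSpec, ROLES

__all__ = [
    "GenotypeMatrix", "TrioCohort", "simulate_founders", "transmit_genotypes",
    "assortative_pairing", "simulate_cohort", "inject_outliers_and_missingness",
    "simulated_gwas",
]

logger = logging.getLogger(__name__)

# physical layout of simulated SNPs: blocks are placed far apart so that
# LD (and the clumping window) never spans blocks
_BLOCK_SPACING_BP = 20_000_000
_SNP_SPACING_BP = 10_000

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]

_HEIGHT_MEAN = {"child": 1.28, "mother": 1.68, "father": 1.81}
_HEIGHT_SD = {"child": 0.055, "mother": 0.06, "father": 0.065}


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP metadata.

    ``snps`` has columns snp_id, chrom, pos (1-based), effect_allele,
    other_allele; dosages count copies of the effect allele.
    """

    ids: np.ndarray
    snps: pd.DataFrame
    dosages: np.ndarray
    subpop: np.ndarray | None = None

    def __post_init__(self):
        d = self.dosages
        if d.shape != (len(self.ids), len(self.snps)):
            raise ValueError("dosage shape does not match ids x snps")
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.snps.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("SNP positions must be strictly increasing within a chromosome")

    def allele_freqs(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, rows) -> "GenotypeMatrix":
        sub = None if self.subpop is None else self.subpop[rows]
        return GenotypeMatrix(self.ids[rows], self.snps, self.dosages[rows], sub)

    def write(self, path) -> None:
        """Tab-delimited: snp_id, chrom, pos, other_allele, effect_allele,
        then one dosage column per individual (SNPs as rows)."""
        out = self.snps[["snp_id", "chrom", "pos", "other_allele", "effect_allele"]].copy()
        body = pd.DataFrame(self.dosages.T, columns=[str(i) for i in self.ids])
        pd.concat([out.reset_index(drop=True), body], axis=1).to_csv(path, sep="\t", index=False)


@dataclass
class TrioCohort:
    """One simulated cohort: per-family phenotypes plus (optionally)
    genotype matrices and the true SNP effect sizes.

    ``df`` carries one row per family (exactly one child, mother, and
    father) with columns: family_id, cluster_id, subpop, child_sex,
    birth_year, confounder, the true standardized scores g_child /
    g_mother / g_father, the instrument columns pgs_* (equal to the
    true scores until polygenic scoring replaces them), role-prefixed
    height / weight / bmi, parental symptom z-scores mother_sym /
    father_sym, and one y_<name> column per outcome.
    """

    df: pd.DataFrame
    config: SimConfig
    genotypes: dict[str, GenotypeMatrix] | None = None
    snp_effects: pd.DataFrame | None = None
    items: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.df)

    def outcome_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("y_")]

    def write_phenotypes(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# founders


def _draw_subpop_freqs(p_anc: np.ndarray, fst: float, n_subpops: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols: subpop frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if fst == 0.0 or n_subpops == 1:
        return np.tile(p_anc, (n_subpops, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    out = rng.beta(np.tile(a, (n_subpops, 1)), np.tile(b, (n_subpops, 1)))
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def _sample_haplotypes(thresholds: np.ndarray, block_size: int, rho: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One haplotype per row: AR(1) latent normal per LD block, thresholded.

    ``thresholds`` is (n_ind, n_snps): allele = 1 where latent < Phi^-1(p).
    """
    n, m = thresholds.shape
    hap = np.empty((n, m), dtype=np.int8)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        w = stop - start
        z = np.empty((n, w))
        z[:, 0] = rng.standard_normal(n)
        for k in range(1, w):
            z[:, k] = rho * z[:, k - 1] + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        hap[:, start:stop] = z < thresholds[:, start:stop]
    return hap


def _make_snp_table(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    eff = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oth = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n_snps)],
        "chrom": 1,
        "pos": 0,
        "effect_allele": eff,
        "other_allele": oth,
    })


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw founder (parental) genotypes.

    Returns a :class:`GenotypeMatrix` with ``2 * n_families`` rows
    (mothers first, then fathers) and per-individual subpopulation
    labels.  Allele frequencies follow the Balding–Nichols construction
    from an ancestral MAF drawn uniformly on ``maf_range``; within-block
    LD is induced by an AR(1) Gaussian copula with latent correlation
    ``ld_rho`` and thresholding to haplotypes; dosages are the sum of
    two independent haplotypes (Hardy–Weinberg within subpopulation).
    """
    if config.n_snps < 1:
        raise ConfigError("simulate_founders requires n_snps >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_families
    n2 = 2 * n
    m = config.n_snps
    p_anc = rng.uniform(*config.maf_range, size=m)
    freqs = _draw_subpop_freqs(p_anc, config.fst, config.n_subpops, rng)
    # balanced labels, aligned between the mother and father halves so that
    # within-subpopulation (endogamous) pairing is always feasible
    labels = rng.permutation(np.arange(n) % config.n_subpops)
    subpop = np.concatenate([labels, labels])
    thresholds = stats.norm.ppf(freqs)[subpop, :]  # (n2, m)
    hap1 = _sample_haplotypes(thresholds, config.ld_block_size, config.ld_rho, rng)
    hap2 = _sample_haplotypes(thresholds, config.ld_block_size, config.ld_rho, rng)
    dosages = (hap1 + hap2).astype(np.int8)

    snps = _make_snp_table(m, rng)
    block = np.arange(m) // config.ld_block_size
    within = np.arange(m) % config.ld_block_size
    snps["pos"] = 1 + block * _BLOCK_SPACING_BP + within * _SNP_SPACING_BP
    ids = np.array([f"M{i}" for i in range(config.n_families)]
                   + [f"F{i}" for i in range(config.n_families)])
    return GenotypeMatrix(ids=ids, snps=snps, dosages=dosages, subpop=subpop)


def transmit_genotypes(mother_dosages: np.ndarray, father_dosages: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: per SNP the child receives
    Bernoulli(d_m / 2) + Bernoulli(d_f / 2) effect alleles.

    Unphased: draws are independent across SNPs, so parental LD is not
    preserved in child haplotypes (acceptable because LD is consumed
    only by clumping on the founder generation).
    """
    dm = np.asarray(mother_dosages)
    df_ = np.asarray(father_dosages)
    for d, who in ((dm, "mother"), (df_, "father")):
        if not np.all(np.isin(np.unique(d), [0, 1, 2])):
            raise ValueError(f"{who} dosages must be hard calls in {{0,1,2}}")
    a = rng.random(dm.shape) < dm / 2.0
    b = rng.random(df_.shape) < df_ / 2.0
    return (a.astype(np.int8) + b.astype(np.int8))


# ---------------------------------------------------------------------------
# assortative mating


def _rank_normal(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.5) / len(x))


def _mating_loadings(targets: dict[tuple[str, str], float],
                     mother_traits: list[str], father_traits: list[str]):
    """Rank-1 factorisation of the target cross-correlation matrix.

    A single latent mating score per person can only realise targets of
    the form a_t * b_s; non-factorisable targets, or loadings implying
    a latent variance above 1, raise with the achievable bound.
    """
    T = np.zeros((len(mother_traits), len(father_traits)))
    for (mt, ft), r in targets.items():
        if mt not in mother_traits or ft not in father_traits:
            raise ValueError(f"unknown mating trait pair {(mt, ft)!r}")
        if abs(r) > 1:
            raise ValueError(f"target correlation {r} for {(mt, ft)} exceeds 1 in magnitude")
        T[mother_traits.index(mt), father_traits.index(ft)] = r
    if not T.any():
        return np.zeros(len(mother_traits)), np.zeros(len(father_traits))
    u, s, vt = np.linalg.svd(T)
    approx = s[0] * np.outer(u[:, 0], vt[0])
    if np.abs(T - approx).max() > 1e-8:
        raise ValueError(
            "spousal correlation targets are not achievable by a single latent "
            "mating score (matrix is not rank-1); best rank-1 approximation "
            f"differs by {np.abs(T - approx).max():.3g}"
        )
    a = u[:, 0] * np.sqrt(s[0])
    b = vt[0] * np.sqrt(s[0])
    # fix sign so mother loadings are predominantly positive
    if a.sum() < 0:
        a, b = -a, -b
    for v, side in ((a, "mother"), (b, "father")):
        nrm = float(v @ v)
        if nrm > 1.0 + 1e-9:
            raise ValueError(
                f"infeasible spousal targets: {side} latent loadings imply "
                f"variance {nrm:.3f} > 1; achievable magnitude bound is "
                f"{1.0 / nrm:.3f} of the requested targets"
            )
    return a, b


def assortative_pairing(mother_traits: pd.DataFrame, father_traits: pd.DataFrame,
                        targets: dict[tuple[str, str], float] | float,
                        rng: np.random.Generator,
                        subpop: np.ndarray | None = None) -> np.ndarray:
    """Pair spouses by Gaussian-copula rank matching on latent mating scores.

    Returns a permutation ``perm`` such that mother ``i`` is paired with
    father ``perm[i]``.  Each parent receives a latent score
    ``sum_t a_t z_t + noise`` (z: rank-normal trait scores); mothers and
    fathers are sorted on their latents within subpopulation and paired
    by rank, which drives the realised cross-correlations to
    ``a_t * b_s``.  Scalar ``targets`` is shorthand for the first trait
    of each frame.
    """
    if len(mother_traits) != len(father_traits):
        raise ValueError("equal numbers of mothers and fathers required")
    mt_names = list(mother_traits.columns)
    ft_names = list(father_traits.columns)
    if not isinstance(targets, dict):
        targets = {(mt_names[0], ft_names[0]): float(targets)}
    a, b = _mating_loadings(targets, mt_names, ft_names)
    n = len(mother_traits)
    if subpop is None:
        subpop = np.zeros(n, dtype=int)

    zm = np.column_stack([_rank_normal(mother_traits[c].to_numpy()) for c in mt_names])
    zf = np.column_stack([_rank_normal(father_traits[c].to_numpy()) for c in ft_names])
    sm = np.sqrt(max(0.0, 1.0 - float(a @ a)))
    sf = np.sqrt(max(0.0, 1.0 - float(b @ b)))
    lat_m = zm @ a + sm * rng.standard_normal(n)
    lat_f = zf @ b + sf * rng.standard_normal(n)

    perm = np.empty(n, dtype=int)
    for s in np.unique(subpop):
        mi = np.where(subpop == s)[0]
        fi = np.where(subpop == s)[0]
        # endogamy requires equal subpop counts on both sides by construction
        order_m = mi[np.argsort(lat_m[mi], kind="stable")]
        order_f = fi[np.argsort(lat_f[fi], kind="stable")]
        perm[order_m] = order_f
    return perm


# ---------------------------------------------------------------------------
# phenotypes


def _subpop_shifts(amplitude: float, n_subpops: int) -> np.ndarray:
    if n_subpops == 1 or amplitude == 0.0:
        return np.zeros(n_subpops)
    raw = np.linspace(-1.0, 1.0, n_subpops) * amplitude
    return raw - raw.mean()


def _bmi_z(g: np.ndarray, r2: float, shift: np.ndarray, conf: np.ndarray,
           c: float, var_shift: float, rng: np.random.Generator) -> np.ndarray:
    resid = 1.0 - r2 - c**2 - var_shift
    if resid <= 0:
        raise ConfigError("implied residual BMI variance is non-positive")
    return (np.sqrt(r2) * g + shift + c * conf
            + np.sqrt(resid) * rng.standard_normal(len(g)))


def _ordinal_items(liability: np.ndarray, spec: OutcomeSpec,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Right-skewed ordinal items from a shared liability (graded thresholds)."""
    n_items, n_cat = spec.n_items, spec.n_categories
    # marginal exceedance probabilities chosen to give the sparse, zero-heavy
    # distributions typical of parent-reported symptom scales
    p_exceed = [0.12, 0.03, 0.01][: n_cat - 1]
    cuts = stats.norm.ppf([1.0 - p for p in p_exceed])
    lam = spec.item_loading
    z = (liability - liability.mean()) / liability.std(ddof=1)
    items = np.zeros((len(z), n_items), dtype=np.int8)
    for j in range(n_items):
        latent = lam * z + np.sqrt(1 - lam**2) * rng.standard_normal(len(z))
        items[:, j] = np.searchsorted(cuts, latent, side="right")
    return pd.DataFrame(items, columns=[f"{spec.name}_item{j + 1}" for j in range(n_items)])


def _adjusted_targets(targets: dict[tuple[str, str], float], shared_frac: float):
    """Deflate copula targets so realised correlations of final BMI match.

    Family-shared BMI components added after pairing (family confounder;
    subpopulation shifts under endogamy) contribute ``shared_frac`` of
    BMI variance to the spousal covariance on their own; the
    within-pairing target is solved from
    r_realised = r_pre * (1 - s) + s.
    """
    out = {}
    s = shared_frac
    for (mt, ft), r in targets.items():
        if mt == "bmi" and ft == "bmi":
            r_pre = (r - s) / (1.0 - s)
            if abs(r_pre) > 1:
                raise ConfigError(
                    f"spousal BMI correlation target {r} is infeasible given the "
                    f"shared family variance fraction {s:.3f}; achievable range is "
                    f"[{2 * s - 1:.3f}, 1]"
                )
            out[(mt, ft)] = r_pre
        elif "bmi" in (mt, ft):
            out[(mt, ft)] = r / np.sqrt(1.0 - s)
        else:
            out[(mt, ft)] = r
    return out


def simulate_cohort(config: SimConfig) -> TrioCohort:
    """Simulate a full trio cohort under ``config``.

    Deterministic given ``config.seed``: two calls with the same config
    produce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_families
    snp_level = config.n_snps > 0

    if snp_level:
        founders = simulate_founders(config, rng)
        beta_true = rng.standard_normal(config.n_snps)
        g_raw = founders.dosages @ beta_true
        mu, sg = g_raw.mean(), g_raw.std(ddof=1)
        g_all = (g_raw - mu) / sg
        g_m, g_f = g_all[:n], g_all[n:]
        # founder subpop labels are aligned between halves (simulate_founders)
        subpop = founders.subpop[:n]
        mothers = founders.subset(np.arange(n))
        fathers = founders.subset(np.arange(n, 2 * n))
        snp_effects = pd.DataFrame({"snp_id": founders.snps["snp_id"],
                                    "beta_true": beta_true,
                                    "freq": founders.allele_freqs(),
                                    "score_center": mu, "score_scale": sg})
    else:
        if config.n_subpops > 1 or config.fst > 0:
            raise ConfigError(
                "score-level fast path (n_snps=0) supports a single "
                "subpopulation only; use SNP-level simulation for stratification"
            )
        g_m = rng.standard_normal(n)
        g_f = rng.standard_normal(n)
        mothers = fathers = None
        subpop = np.zeros(n, dtype=int)
        snp_effects = None

    c = config.confounder_sd
    shifts_b = _subpop_shifts(config.strat_shift_bmi, config.n_subpops)
    var_shift_b = float(np.mean(shifts_b**2))
    shift_b = shifts_b[subpop]

    # pre-pairing parental BMI z-scores; the family confounder's share of
    # variance (c^2) is reserved here and added after pairing, keeping the
    # genetic variance fraction exactly pgs_r2
    r2c, r2m, r2f = config.role_r2()
    pre_m = _bmi_z(g_m, r2m, shift_b, np.zeros(n), 0.0, var_shift_b + c**2, rng)
    pre_f = _bmi_z(g_f, r2f, shift_b, np.zeros(n), 0.0, var_shift_b + c**2, rng)
    # parental symptom phenotypes (standardized; used for mating and diagnostics)
    sym_m = rng.standard_normal(n)
    sym_f = rng.standard_normal(n)

    shared_frac = c**2 + var_shift_b
    targets = _adjusted_targets(config.spousal_targets(), shared_frac)
    perm = assortative_pairing(
        pd.DataFrame({"bmi": pre_m, "symptoms": sym_m}),
        pd.DataFrame({"bmi": pre_f, "symptoms": sym_f}),
        targets, rng, subpop=subpop,
    )
    # reorder fathers to their assigned mothers
    g_f = g_f[perm]
    pre_f = pre_f[perm]
    sym_f = sym_f[perm]
    if snp_level:
        fathers = fathers.subset(perm)

    # sibships: a fraction of couples contribute a second child (extra family
    # rows sharing cluster_id and parents)
    couple_idx = np.arange(n)
    if config.sibship_rate > 0:
        n_extra = int(round(config.sibship_rate * n))
        extra = rng.choice(n, size=n_extra, replace=False)
        couple_idx = np.concatenate([couple_idx, extra])
    nf = len(couple_idx)

    # C_fam is drawn once per couple and shared by every trio member
    # (and by sibling rows of the same couple)
    conf_by_couple = rng.standard_normal(n)
    conf = conf_by_couple[couple_idx]

    # children
    if snp_level:
        child_dos = transmit_genotypes(mothers.dosages[couple_idx],
                                       fathers.dosages[couple_idx], rng)
        g_c = child_dos @ snp_effects["beta_true"].to_numpy()
        g_c = (g_c - snp_effects["score_center"].iloc[0]) / snp_effects["score_scale"].iloc[0]
        child_geno = GenotypeMatrix(
            ids=np.array([f"C{i}" for i in range(nf)]),
            snps=mothers.snps, dosages=child_dos, subpop=subpop[couple_idx],
        )
    else:
        g_c = (g_m[couple_idx] + g_f[couple_idx]) / 2.0 \
            + np.sqrt(0.5) * rng.standard_normal(nf)
        child_geno = None

    sub_fam = subpop[couple_idx]
    shift_b_fam = shifts_b[sub_fam]
    zc = _bmi_z(g_c, r2c, shift_b_fam, conf, c, var_shift_b, rng)

    mean_c, mean_m, mean_f = config.bmi_mean
    sd_c, sd_m, sd_f = config.bmi_sd
    bmi_c = mean_c + sd_c * zc
    bmi_m = mean_m + sd_m * (pre_m[couple_idx] + c * conf)
    bmi_f = mean_f + sd_f * (pre_f[couple_idx] + c * conf)

    df = pd.DataFrame({
        "family_id": np.arange(nf),
        "cluster_id": couple_idx,
        "subpop": sub_fam,
        "child_sex": rng.integers(0, 2, size=nf),
        "birth_year": rng.integers(2000, 2009, size=nf),
        "confounder": conf,
        "g_child": g_c, "g_mother": g_m[couple_idx], "g_father": g_f[couple_idx],
        "child_bmi": bmi_c, "mother_bmi": bmi_m, "father_bmi": bmi_f,
        "mother_sym": sym_m[couple_idx], "father_sym": sym_f[couple_idx],
    })
    # instrument columns default to the true scores; polygenic scoring
    # replaces them when a weight table is used
    for role in ROLES:
        df[f"pgs_{role}"] = df[f"g_{role}"]

    # height/weight consistent with BMI (weight = bmi * height^2)
    for role, bmi in (("child", bmi_c), ("mother", bmi_m), ("father", bmi_f)):
        h = _HEIGHT_MEAN[role] + _HEIGHT_SD[role] * rng.standard_normal(nf)
        df[f"{role}_height"] = h
        df[f"{role}_weight"] = bmi * h**2

    # outcomes
    items: dict[str, pd.DataFrame] = {}
    for spec in config.resolved_outcomes():
        shifts_o = _subpop_shifts(spec.strat_shift, config.n_subpops)
        c_out = c if spec.confounder_load is None else spec.confounder_load
        var_noise = 1.0 - c_out**2 - float(np.mean(shifts_o**2))
        if var_noise <= 0:
            raise ConfigError(f"outcome {spec.name}: non-positive residual variance")
        y = (spec.beta_child * bmi_c / 5.0
             + spec.alpha_mother * bmi_m / 5.0
             + spec.alpha_father * bmi_f / 5.0
             + spec.theta_pleio * g_c
             + shifts_o[sub_fam]
             + c_out * conf
             + np.sqrt(var_noise) * rng.standard_normal(nf))
        df[f"y_{spec.name}"] = y
        if spec.n_items:
            items[spec.name] = _ordinal_items(y, spec, rng)

    genotypes = None
    if snp_level:
        genotypes = {"child": child_geno,
                     "mother": mothers.subset(couple_idx),
                     "father": fathers.subset(couple_idx)}
    return TrioCohort(df=df, config=config, genotypes=genotypes,
                      snp_effects=snp_effects, items=items)


# ---------------------------------------------------------------------------
# corruption for cleaning tests


def inject_outliers_and_missingness(cohort: TrioCohort, outlier_rate: float = 0.0,
                                    missing_rate: float = 0.0,
                                    columns: tuple[str, ...] = ("child_height", "child_weight"),
                                    magnitude_sd: float = 10.0,
                                    seed: int = 0):
    """Corrupt a stated fraction of anthropometric values.

    Outliers are shifted by ``magnitude_sd`` standard deviations (so the
    4-SD cleaning rule flags them); missingness is set to NaN.  Returns
    the corrupted cohort and a corruption log.
    """
    if not (0 <= outlier_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    log_rows = []
    for col in columns:
        x = df[col].to_numpy(float).copy()
        n = len(x)
        n_out = int(round(outlier_rate * n))
        n_mis = int(round(missing_rate * n))
        idx = rng.permutation(n)
        out_idx, mis_idx = idx[:n_out], idx[n_out:n_out + n_mis]
        sd = np.nanstd(x, ddof=1)
        sign = rng.choice([-1.0, 1.0], size=n_out)
        for i, s in zip(out_idx, sign):
            log_rows.append({"row": int(i), "column": col, "kind": "outlier",
                             "original": x[i]})
            x[i] = x[i] + s * magnitude_sd * sd
        for i in mis_idx:
            log_rows.append({"row": int(i), "column": col, "kind": "missing",
                             "original": x[i]})
            x[i] = np.nan
        df[col] = x
    log = pd.DataFrame(log_rows, columns=["row", "column", "kind", "original"])
    return TrioCohort(df=df, config=cohort.config, genotypes=cohort.genotypes,
                      snp_effects=cohort.snp_effects, items=cohort.items), log


# ---------------------------------------------------------------------------
# simulated GWAS weight tables


def simulated_gwas(cohort: TrioCohort, gwas_se: float = 0.003,
                   seed: int = 0, label: str = "adult BMI") -> pd.DataFrame:
    """Noisy per-allele GWAS summary rows for the cohort's causal SNPs.

    Observed beta = true per-allele effect on (adult) BMI + N(0, se);
    p-values from the normal z statistic.  Returns a weight-table frame
    (snp_id, chromosome, position, effect_allele, other_allele, beta,
    se, p_value) consumable by the scoring module.
    """
    if cohort.snp_effects is None or cohort.genotypes is None:
        raise ValueError("simulated_gwas requires a SNP-level cohort")
    rng = np.random.default_rng(seed)
    snps = cohort.genotypes["mother"].snps
    eff = cohort.snp_effects
    sd_adult = cohort.config.bmi_sd[1]
    r2 = cohort.config.pgs_r2_mother
    true_per_allele = sd_adult * np.sqrt(r2) * eff["beta_true"].to_numpy() / eff["score_scale"].iloc[0]
    beta_hat = true_per_allele + gwas_se * rng.standard_normal(len(eff))
    z = beta_hat / gwas_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "snp_id": snps["snp_id"],
        "chromosome": snps["chrom"],
        "position": snps["pos"],
        "effect_allele": snps["effect_allele"],
        "other_allele": snps["other_allele"],
        "beta": beta_hat,
        "se": gwas_se,
        "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
        "provenance": label,
    })
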