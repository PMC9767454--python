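"""Pleiotropy-robust summary-statistic MR estimators and diagnostics.

Works on per-SNP association pairs (SNP-exposure effects from a GWAS
weight table; SNP-outcome effects estimated in-cohort, optionally
adjusted for parental genotype at the same SNP) and implements the
standard sensitivity battery: inverse-variance weighted regression
through the origin, MR-Egger with a free intercept estimating average
directional pleiotropy, the weighted median, and the mode-based
estimator — plus spousal phenotype/score regressions quantifying
assortative mating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import EstimateRecord, LinearModel
from .simulate import GenotypeMatrix

__all__ = [
    "SnpSummary", "snp_outcome_assoc", "harmonize", "make_snp_summaries",
    "ivw", "egger", "weighted_median", "mode_based", "assortment_diagnostics",
]

logger = logging.getLogger(__name__)

SNPSUMMARY_COLUMNS = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]


@dataclass(frozen=True)
class SnpSummary:
    """Harmonized per-SNP exposure and outcome association estimates."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float

    def __post_init__(self):
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


def _as_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([s.__dict__ for s in summaries])
    missing = [c for c in SNPSUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP summaries lack columns {missing}")
    if (df["se_exp"] <= 0).any() or (df["se_out"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return df


def harmonize(summaries) -> pd.DataFrame:
    """Orient every SNP so the exposure beta is positive (Egger
    convention); both betas flip sign together."""
    df = _as_frame(summaries)
    flip = df["beta_exp"] < 0
    df.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
    return df


# ---------------------------------------------------------------------------
# SNP-outcome associations


def snp_outcome_assoc(child: GenotypeMatrix, outcome: np.ndarray,
                      covariates: pd.DataFrame | None = None,
                      mother: GenotypeMatrix | None = None,
                      father: GenotypeMatrix | None = None,
                      adjust_parental: bool = False) -> pd.DataFrame:
    """Per-SNP robust-SE regression of the outcome on the child's dosage.

    With ``adjust_parental`` the mother's and father's dosages at the
    same SNP enter as covariates, which removes dynastic and
    demographic contributions to the SNP-outcome association.
    Monomorphic SNPs are skipped with a log entry.
    """
    if adjust_parental and (mother is None or father is None):
        raise ValueError("parental genotype matrices required when adjust_parental=True")
    y = np.asarray(outcome, float)
    keep = ~np.isnan(y)
    C = covariates.to_numpy(float)[keep] if covariates is not None else None
    rows = []
    for j, snp in enumerate(child.snps["snp_id"]):
        d = child.dosages[keep, j].astype(float)
        if d.std(ddof=1) == 0:
            logger.info("snp_outcome_assoc: %s monomorphic, skipped", snp)
            continue
        cols = [d]
        names = ["dosage"]
        if adjust_parental:
            cols += [mother.dosages[keep, j].astype(float),
                     father.dosages[keep, j].astype(float)]
            names += ["dosage_mother", "dosage_father"]
        X = np.column_stack(cols if C is None else cols + [C])
        nm = names + ([f"c{i}" for i in range(C.shape[1])] if C is not None else [])
        res = LinearModel(y[keep], X, names=nm).fit()
        rows.append({"snp_id": snp, "beta_out": float(res.params["dosage"]),
                     "se_out": float(res.bse["dosage"])})
    return pd.DataFrame(rows)


def make_snp_summaries(weights: pd.DataFrame, outcome_assoc: pd.DataFrame) -> pd.DataFrame:
    """Join GWAS exposure effects with in-cohort outcome effects and
    harmonize orientation."""
    w = weights.rename(columns={"beta": "beta_exp", "se": "se_exp"})
    df = w[["snp_id", "beta_exp", "se_exp"]].merge(outcome_assoc, on="snp_id")
    return harmonize(df)


# ---------------------------------------------------------------------------
# estimators


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares; returns coef, cov (multiplicative
    random-effects scaling, floored at 1), and the weighted RSS."""
    D = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    W = w[:, None]
    DtWD = D.T @ (W * D)
    coef = np.linalg.solve(DtWD, D.T @ (w * y))
    resid = y - D @ coef
    rss_w = float(np.sum(w * resid**2))
    k, p = len(y), D.shape[1]
    scale = max(1.0, rss_w / (k - p)) if k > p else 1.0
    cov = scale * np.linalg.inv(DtWD)
    return coef, cov, rss_w


def ivw(summaries, n: int | None = None,
        random_effects: bool | str = "auto") -> EstimateRecord:
    """Inverse-variance weighted estimate: slope of beta_out on beta_exp
    through the origin with weights 1/se_out^2.

    With ``random_effects="auto"`` the SE is scaled multiplicatively
    (Cochran's Q over k-1) when heterogeneity exceeds its degrees of
    freedom; ``False`` forces the fixed-effect SE, ``True`` always
    applies the scaling.
    """
    df = harmonize(summaries)
    if len(df) < 2:
        raise ValueError("ivw requires at least 2 SNPs")
    x = df["beta_exp"].to_numpy()
    y = df["beta_out"].to_numpy()
    w = 1.0 / df["se_out"].to_numpy() ** 2
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / sxx
    q = float(np.sum(w * (y - beta * x) ** 2))
    k = len(df)
    scale = q / (k - 1)
    if random_effects == "auto":
        scale = max(1.0, scale)
    elif not random_effects:
        scale = 1.0
    se = float(np.sqrt(scale / sxx))
    return EstimateRecord(term="child_bmi", beta=beta, se=se, estimator="ivw",
                          n=n or len(df), scale="per_unit_exposure")


def cochran_q(summaries) -> dict:
    """Heterogeneity of per-SNP estimates about the IVW slope."""
    df = harmonize(summaries)
    w = 1.0 / df["se_out"].to_numpy() ** 2
    coef, _, q = _wls(df["beta_exp"].to_numpy(), df["beta_out"].to_numpy(), w,
                      intercept=False)
    k = len(df)
    return {"Q": q, "df": k - 1, "p": float(stats.chi2.sf(q, k - 1))}


def egger(summaries, n: int | None = None) -> dict[str, EstimateRecord]:
    """MR-Egger: weighted regression of beta_out on beta_exp with a free
    intercept; the intercept estimates average directional pleiotropy
    per SNP.  Exposure betas must be oriented positive (pre-harmonized
    inputs are re-checked)."""
    df = _as_frame(summaries)
    if len(df) < 3:
        raise ValueError("egger requires at least 3 SNPs")
    if (df["beta_exp"] < 0).any():
        raise ValueError("egger requires exposure betas oriented positive; harmonize first")
    w = 1.0 / df["se_out"].to_numpy() ** 2
    coef, cov, _ = _wls(df["beta_exp"].to_numpy(), df["beta_out"].to_numpy(), w,
                        intercept=True)
    k = n or len(df)
    return {
        "intercept": EstimateRecord(term="egger_intercept", beta=float(coef[0]),
                                    se=float(np.sqrt(cov[0, 0])),
                                    estimator="egger_intercept", n=k,
                                    scale="per_snp"),
        "slope": EstimateRecord(term="child_bmi", beta=float(coef[1]),
                                se=float(np.sqrt(cov[1, 1])),
                                estimator="egger_slope", n=k,
                                scale="per_unit_exposure"),
    }


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(summaries, n_boot: int = 1000, seed: int = 0,
                    n: int | None = None) -> EstimateRecord:
    """Weighted median of per-SNP Wald ratios (inverse-variance weights).

    Consistent when at least half the weight comes from valid
    instruments.  SE by parametric bootstrap of the ratios (normal
    perturbations with the first-order ratio SEs), replicate count and
    seed recorded in the estimate metadata via determinism of ``seed``.
    """
    df = harmonize(summaries)
    if len(df) < 3:
        raise ValueError("weighted_median requires at least 3 SNPs")
    ratios = (df["beta_out"] / df["beta_exp"]).to_numpy()
    se_r = (df["se_out"] / df["beta_exp"].abs()).to_numpy()
    w = 1.0 / se_r**2
    est = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median_point(ratios + se_r * rng.standard_normal(len(ratios)), w)
    return EstimateRecord(term="child_bmi", beta=est, se=float(boots.std(ddof=1)),
                          estimator="wmedian", n=n or len(df),
                          scale="per_unit_exposure")


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    wn = weights / weights.sum()

    def dens(x):
        return float(np.sum(wn * np.exp(-0.5 * ((x - ratios) / bandwidth) ** 2)))

    grid = np.linspace(ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth, 1024)
    vals = np.zeros_like(grid)
    for r, wi in zip(ratios, wn):
        vals += wi * np.exp(-0.5 * ((grid - r) / bandwidth) ** 2)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda x: -dens(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def _silverman_bandwidth(ratios: np.ndarray) -> float:
    s = ratios.std(ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    if spread == 0:
        return 0.0
    return 0.9 * spread * len(ratios) ** (-0.2)


def mode_based(summaries, bandwidth_factor: float = 1.0, n_boot: int = 1000,
               seed: int = 0, n: int | None = None) -> EstimateRecord:
    """Mode-based estimate: mode of the normal-kernel-smoothed weighted
    Wald-ratio density, bandwidth = factor x modified Silverman rule.

    Consistent when the largest group of SNPs sharing a ratio are valid
    (zero modal pleiotropy assumption).  SE by parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    df = harmonize(summaries)
    if len(df) < 3:
        raise ValueError("mode_based requires at least 3 SNPs")
    ratios = (df["beta_out"] / df["beta_exp"]).to_numpy()
    se_r = (df["se_out"] / df["beta_exp"].abs()).to_numpy()
    w = 1.0 / se_r**2
    h = bandwidth_factor * _silverman_bandwidth(ratios)
    if h == 0:  # all ratios identical
        return EstimateRecord(term="child_bmi", beta=float(ratios[0]), se=0.0,
                              estimator="mode", n=n or len(df),
                              scale="per_unit_exposure")
    est = _mode_point(ratios, w, h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rb = ratios + se_r * rng.standard_normal(len(ratios))
        hb = bandwidth_factor * _silverman_bandwidth(rb)
        boots[b] = _mode_point(rb, w, hb) if hb > 0 else rb[0]
    return EstimateRecord(term="child_bmi", beta=est, se=float(boots.std(ddof=1)),
                          estimator="mode", n=n or len(df),
                          scale="per_unit_exposure")


# ---------------------------------------------------------------------------
# assortative-mating diagnostics


def assortment_diagnostics(cohort: pd.DataFrame,
                           mother_traits: tuple[str, ...] = ("mother_bmi", "mother_sym"),
                           father_traits: tuple[str, ...] = ("father_bmi", "father_sym"),
                           covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """All pairwise cross-spouse regressions on standardized traits.

    Each father trait is regressed on each mother trait (both
    standardized within role) with robust SEs and optional
    covariate adjustment (e.g. ancestry components); returns a labelled
    grid of coefficients mirroring the spousal-association analysis.
    """
    rows = []
    df = cohort
    for ft in father_traits:
        if ft not in df.columns:
            raise ValueError(f"missing father trait column {ft!r}")
    for mt in mother_traits:
        if mt not in df.columns:
            raise ValueError(f"missing mother trait column {mt!r}")
    for ft in father_traits:
        y = df[ft].to_numpy(float)
        y = (y - y.mean()) / y.std(ddof=1)
        for mt in mother_traits:
            x = df[mt].to_numpy(float)
            x = (x - x.mean()) / x.std(ddof=1)
            cols = [x] + [df[c].to_numpy(float) for c in covariates]
            res = LinearModel(y, np.column_stack(cols),
                              names=[mt, *covariates]).fit()
            rows.append({
                "father_trait": ft, "mother_trait": mt,
                "beta": float(res.params[mt]), "se": float(res.bse[mt]),
                "ci_low": float(res.conf_int().loc[mt, "ci_low"]),
                "ci_high": float(res.conf_int().loc[mt, "ci_high"]),
                "p": float(res.pvalues[mt]), "n": res.nobs,
            })
    return pd.DataFrame(rows)
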