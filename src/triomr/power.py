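"""Simulation-based power and minimum-detectable-effect analysis.

Estimates, by repeated simulation and refitting, the rejection rate of
the child-BMI term for the OLS, classic-MR, and within-family-MR
designs at a given effect size, and inverts it (bisection with common
random numbers) to the minimum effect detectable with a target power.
The analytic normal-theory approximation
``MDE ~ (z_{1-alpha/2} + z_{power}) x SE ~ 2.8 x SE`` at 80% power is
computed alongside as a cross-check.

Replicate cohorts use the score-level fast path (the polygenic score
is the true score), so power reflects instrument strength through the
configured PGS-on-BMI R^2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .config import SimConfig
from .mr import classic_mr, fit_ols, ols_spec, within_family_mr
from .simulate import simulate_cohort

__all__ = ["PowerQuery", "PowerEstimate", "MDEResult",
           "estimate_power", "minimum_detectable_effect", "power_curve"]

_DESIGNS = ("classic", "within_family", "ols")


@dataclass(frozen=True)
class PowerQuery:
    """One power question: design, cohort size, instrument strength, alpha."""

    design: str = "classic"
    n_families: int = 40949
    pgs_r2: tuple[float, float, float] = (0.017, 0.032, 0.030)  # child, mother, father
    bmi_sd: tuple[float, float, float] = (2.0, 4.1, 3.2)
    alpha: float = 0.05
    target_power: float = 0.8
    replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}")
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if self.replicates < 100:
            raise ValueError("at least 100 replicates required for reported results")

    def base_config(self, effect: float, seed: int) -> SimConfig:
        cfg = SimConfig.global_null(
            n_families=self.n_families, n_snps=0, seed=seed,
            pgs_r2_child=self.pgs_r2[0], pgs_r2_mother=self.pgs_r2[1],
            pgs_r2_father=self.pgs_r2[2], bmi_sd=self.bmi_sd,
        )
        return replace(cfg, beta_child=float(effect))


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    effect: float
    replicates: int
    failures: int = 0


@dataclass(frozen=True)
class MDEResult:
    simulated: float
    analytic: float
    target_power: float
    design: str
    n_families: int
    evaluations: list = field(default_factory=list)


def _child_record(query: PowerQuery, cohort_df):
    if query.design == "classic":
        return classic_mr(cohort_df, "y_symptoms", cluster=None, transform="none")
    if query.design == "within_family":
        return within_family_mr(cohort_df, "y_symptoms", cluster=None,
                                transform="none")["child"]
    recs = fit_ols(ols_spec("y_symptoms", cluster=None, transform="none"), cohort_df)
    return next(r for r in recs if r.term == "child_bmi")


def _replicate_seeds(query: PowerQuery) -> np.ndarray:
    # common random numbers: the same replicate seeds are reused at every
    # effect size, making power monotone in effect along the bisection path
    ss = np.random.SeedSequence(query.seed)
    return np.array([int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(query.replicates)])


def estimate_power(query: PowerQuery, effect: float,
                   _seeds: np.ndarray | None = None) -> PowerEstimate:
    """Fraction of replicates rejecting the null for the child-BMI term.

    ``effect`` is in SD outcome per 5 kg/m^2.  Failed replicates
    (singular fits) are excluded with a count.  The binomial 95%
    Wilson interval quantifies Monte-Carlo uncertainty.
    """
    seeds = _seeds if _seeds is not None else _replicate_seeds(query)
    rejections = 0
    failures = 0
    for s in seeds:
        cfg = query.base_config(effect, int(s))
        try:
            cohort = simulate_cohort(cfg)
            rec = _child_record(query, cohort.df)
        except np.linalg.LinAlgError:
            failures += 1
            continue
        if rec.p < query.alpha:
            rejections += 1
    m = len(seeds) - failures
    if m == 0:
        raise RuntimeError("all replicates failed")
    phat = rejections / m
    lo, hi = _wilson(rejections, m)
    return PowerEstimate(power=phat, ci_low=lo, ci_high=hi, effect=effect,
                         replicates=m, failures=failures)


def _wilson(x: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    p = x / n
    den = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / den
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
    return float(centre - half), float(centre + half)


def analytic_se(query: PowerQuery, n_pilot: int = 20) -> float:
    """Asymptotic SE of the child term from a few null replicates."""
    seeds = _replicate_seeds(query)[:n_pilot]
    ses = []
    for s in seeds:
        cohort = simulate_cohort(query.base_config(0.0, int(s)))
        ses.append(_child_record(query, cohort.df).se)
    return float(np.mean(ses))


def minimum_detectable_effect(query: PowerQuery,
                              bounds: tuple[float, float] | None = None,
                              tol: float = 0.005,
                              max_iter: int = 12) -> MDEResult:
    """Smallest effect detected with ``target_power`` at level ``alpha``.

    Bisection on the effect size using a shared replicate seed set
    (common random numbers); also returns the analytic approximation
    ``(z_{1-alpha/2} + z_{power}) x SE`` for cross-checking.
    """
    se = analytic_se(query)
    z_need = stats.norm.ppf(1 - query.alpha / 2) + stats.norm.ppf(query.target_power)
    analytic = z_need * se
    if bounds is None:
        bounds = (analytic / 2.0, analytic * 2.0)
    lo, hi = bounds
    seeds = _replicate_seeds(query)
    evals = []
    p_lo = estimate_power(query, lo, _seeds=seeds)
    p_hi = estimate_power(query, hi, _seeds=seeds)
    evals += [p_lo, p_hi]
    if not (p_lo.power < query.target_power <= p_hi.power):
        raise ValueError(
            f"bounds {bounds} do not bracket the target power "
            f"({p_lo.power:.2f} .. {p_hi.power:.2f}); widen the grid"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = estimate_power(query, mid, _seeds=seeds)
        evals.append(p_mid)
        if p_mid.power < query.target_power:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return MDEResult(simulated=0.5 * (lo + hi), analytic=float(analytic),
                     target_power=query.target_power, design=query.design,
                     n_families=query.n_families, evaluations=evals)


def power_curve(query: PowerQuery, effects) -> list[PowerEstimate]:
    """Rejection rate over a grid of effect sizes (shared seeds)."""
    seeds = _replicate_seeds(query)
    return [estimate_power(query, float(e), _seeds=seeds) for e in effects]
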