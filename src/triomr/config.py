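"""Generative configuration for trio-cohort simulation.

The simulator emulates a Norwegian-style pregnancy cohort of
mother-father-child trios with SNP dosage genotypes, BMI for every
family member, and continuous child symptom outcomes.  The default
configuration reproduces the observable features of the analysed
sample: 40,949 trios, child BMI 16.3 (SD 2.0), maternal BMI 24.0
(SD 4.1), paternal BMI 25.9 (SD 3.2), a spousal BMI correlation of
0.23, and a BMI polygenic score explaining 1.7% / 3.2% / 3.0% of BMI
variance for children / mothers / fathers.  Bias structures —
population stratification, dynastic (genetic-nurture) effects, and
assortative mating — are switched on through explicit scenario
constructors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np

__all__ = ["OutcomeSpec", "SimConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid generative configuration; the message names the field."""


@dataclass(frozen=True)
class OutcomeSpec:
    """One continuous symptom outcome (optionally with ordinal items).

    Effects are on the standard-deviation scale of the outcome liability
    per 5 kg/m^2 of BMI (the reporting unit used throughout the package).

    Parameters
    ----------
    beta_child
        Causal effect of the child's own BMI.
    alpha_mother, alpha_father
        Dynastic effects of parental BMI acting through the rearing
        environment (not through transmitted alleles).
    theta_pleio
        Direct (horizontally pleiotropic) effect of the child's
        standardized true polygenic score on the outcome.
    strat_shift
        Amplitude of per-subpopulation mean shifts of the outcome
        (SD units); shifts are evenly spaced in [-strat_shift, +strat_shift].
    confounder_load
        Loading of the shared family confounder on the outcome (SD units);
        ``None`` inherits ``SimConfig.confounder_sd``.
    n_items, n_categories
        If set, ordinal questionnaire items are generated so that
        prorated-scale scoring can be exercised (e.g. 13 items with 3
        categories for a short mood-and-feelings analogue).
    """

    name: str = "symptoms"
    beta_child: float = 0.0
    alpha_mother: float = 0.0
    alpha_father: float = 0.0
    theta_pleio: float = 0.0
    strat_shift: float = 0.0
    confounder_load: float | None = None
    n_items: int | None = None
    n_categories: int | None = None
    item_loading: float = 0.7


# role order used throughout the package
ROLES = ("child", "mother", "father")


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of the trio-cohort simulator.

    ``n_snps = 0`` selects the fast score-level path: true polygenic
    scores are drawn directly (parents standard normal; child =
    mid-parent plus segregation noise of variance 1/2) and no genotype
    matrix is produced.  Any positive ``n_snps`` selects the full
    SNP-level path with Balding–Nichols subpopulation structure and
    per-SNP Mendelian transmission.
    """

    n_families: int = 40949
    n_snps: int = 954
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    strat_shift_bmi: float = 0.0
    strat_shift_outcome: float = 0.0
    pgs_r2_child: float = 0.017
    pgs_r2_mother: float = 0.032
    pgs_r2_father: float = 0.030
    # scalar = mother-BMI x father-BMI target; a mapping allows cross-trait
    # targets over {"bmi", "symptoms"} per parent, e.g. {("bmi", "symptoms"): 0.03}
    spousal_corr: float | Mapping[tuple[str, str], float] = 0.23
    beta_child: float = 0.26
    alpha_mother: float = 0.11
    alpha_father: float = 0.0
    theta_pleio: float = 0.0
    confounder_sd: float = 0.2
    bmi_mean: tuple[float, float, float] = (16.3, 24.0, 25.9)  # child, mother, father
    bmi_sd: tuple[float, float, float] = (2.0, 4.1, 3.2)
    outcomes: tuple[OutcomeSpec, ...] | None = None
    sibship_rate: float = 0.0
    seed: int = 0

    # -- validation ----------------------------------------------------

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_snps < 0:
            raise ConfigError("n_snps must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not (0.0 <= self.fst < 0.5):
            raise ConfigError(f"fst must be in [0, 0.5), got {self.fst}")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        for fld in ("pgs_r2_child", "pgs_r2_mother", "pgs_r2_father"):
            v = getattr(self, fld)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{fld} must be in [0, 1), got {v}")
        if not (0.0 <= self.sibship_rate <= 1.0):
            raise ConfigError("sibship_rate must be in [0, 1]")
        # residual BMI variance must stay positive for every role
        for role, r2 in zip(ROLES, self.role_r2()):
            if r2 + self.confounder_sd**2 >= 1.0:
                raise ConfigError(
                    f"implied residual BMI variance for {role} is non-positive "
                    f"(pgs_r2 + confounder_sd^2 >= 1)"
                )

    # -- helpers -------------------------------------------------------

    def role_r2(self) -> tuple[float, float, float]:
        return (self.pgs_r2_child, self.pgs_r2_mother, self.pgs_r2_father)

    def resolved_outcomes(self) -> tuple[OutcomeSpec, ...]:
        """Outcome list; a single outcome from top-level effect fields by default."""
        if self.outcomes is not None:
            return self.outcomes
        return (
            OutcomeSpec(
                name="symptoms",
                beta_child=self.beta_child,
                alpha_mother=self.alpha_mother,
                alpha_father=self.alpha_father,
                theta_pleio=self.theta_pleio,
                strat_shift=self.strat_shift_outcome,
            ),
        )

    def spousal_targets(self) -> dict[tuple[str, str], float]:
        if isinstance(self.spousal_corr, Mapping):
            return dict(self.spousal_corr)
        return {("bmi", "bmi"): float(self.spousal_corr)}

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("spousal_corr"), dict):
            d["spousal_corr"] = {f"{k[0]}:{k[1]}": v for k, v in d["spousal_corr"].items()}
        return d

    # -- scenario constructors ----------------------------------------

    @classmethod
    def global_null(cls, n_families: int = 10000, n_snps: int = 0, seed: int = 0,
                    **kw) -> "SimConfig":
        """No causal effects, no confounding, random mating, one subpopulation."""
        return cls(
            n_families=n_families, n_snps=n_snps, seed=seed,
            spousal_corr=0.0, beta_child=0.0, alpha_mother=0.0, alpha_father=0.0,
            theta_pleio=0.0, confounder_sd=0.0,
            n_subpops=1, fst=0.0, strat_shift_bmi=0.0, strat_shift_outcome=0.0,
            **kw,
        )

    @classmethod
    def dynastic(cls, alpha_mother: float = 0.2, alpha_father: float = 0.2,
                 beta_child: float = 0.1, n_families: int = 40949,
                 n_snps: int = 0, seed: int = 0, pgs_r2: float = 0.02,
                 bmi_sd: float = 2.0, **kw) -> "SimConfig":
        """Dynastic-only bias structure: parental BMI shapes the child's
        outcome through the environment, under random mating.

        Roles are exchangeable (equal PGS R^2 and BMI SD for child,
        mother, father), which is the condition under which classic MR
        has the closed-form probability limit
        beta_child + (alpha_mother + alpha_father) / 2
        while the within-family child term stays consistent.
        """
        return cls(
            n_families=n_families, n_snps=n_snps, seed=seed,
            spousal_corr=0.0, beta_child=beta_child,
            alpha_mother=alpha_mother, alpha_father=alpha_father,
            theta_pleio=0.0, confounder_sd=0.0,
            pgs_r2_child=pgs_r2, pgs_r2_mother=pgs_r2, pgs_r2_father=pgs_r2,
            bmi_sd=(bmi_sd, bmi_sd, bmi_sd),
            n_subpops=1, fst=0.0, strat_shift_bmi=0.0, strat_shift_outcome=0.0,
            **kw,
        )

    @classmethod
    def assortative(cls, spousal_corr: float = 0.23, n_families: int = 40949,
                    n_snps: int = 0, seed: int = 0, **kw) -> "SimConfig":
        """Assortment-only structure: spouses match on BMI, no causal effects."""
        return cls(
            n_families=n_families, n_snps=n_snps, seed=seed,
            spousal_corr=spousal_corr, beta_child=0.0, alpha_mother=0.0,
            alpha_father=0.0, theta_pleio=0.0, confounder_sd=0.0,
            n_subpops=1, fst=0.0, strat_shift_bmi=0.0, strat_shift_outcome=0.0,
            **kw,
        )

    @classmethod
    def stratified(cls, fst: float = 0.1, n_subpops: int = 2,
                   strat_shift_bmi: float = 0.3, strat_shift_outcome: float = 0.3,
                   n_families: int = 10000, n_snps: int = 400, seed: int = 0,
                   **kw) -> "SimConfig":
        """Stratification-only structure: allele frequencies and trait means
        both differ between ancestral subpopulations (gene-environment
        correlation), no causal effects, random mating within subpopulation."""
        if n_snps == 0:
            raise ConfigError("stratified scenarios require SNP-level simulation (n_snps > 0)")
        return cls(
            n_families=n_families, n_snps=n_snps, seed=seed,
            n_subpops=n_subpops, fst=fst,
            strat_shift_bmi=strat_shift_bmi, strat_shift_outcome=strat_shift_outcome,
            spousal_corr=0.0, beta_child=0.0, alpha_mother=0.0, alpha_father=0.0,
            theta_pleio=0.0, confounder_sd=0.0,
            **kw,
        )

    @classmethod
    def moba_like(cls, n_families: int = 40949, n_snps: int = 954,
                  seed: int = 0, **kw) -> "SimConfig":
        """Full cohort emulation with three symptom scales.

        Causal defaults are the within-family point estimates for the
        adult-BMI score analysis: depressive-symptom analogue
        beta_child=0.26 with a maternal dynastic effect 0.11, anxiety
        analogue null, ADHD analogue beta_child=0.36.
        """
        outcomes = (
            OutcomeSpec("smfq", beta_child=0.26, alpha_mother=0.11,
                        n_items=13, n_categories=3),
            OutcomeSpec("scared", n_items=5, n_categories=3),
            OutcomeSpec("rsdbd", beta_child=0.36, n_items=18, n_categories=4),
        )
        return cls(n_families=n_families, n_snps=n_snps, seed=seed,
                   outcomes=outcomes, **kw)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
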