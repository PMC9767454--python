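"""Classic and within-family Mendelian randomization model builders.

Thin, opinionated constructors over :class:`~triomr.regression.LinearModel`
and :class:`~triomr.regression.TrioIVModel`:

* ``fit_ols`` — multivariable regression of the child outcome on the
  three BMI terms plus covariates (the non-genetic comparator).
* ``classic_mr`` — 2SLS with the child's polygenic score instrumenting
  the child's BMI, no parental-genotype adjustment.
* ``within_family_mr`` — multivariable 2SLS with the trio's three
  polygenic scores instrumenting the three BMI exposures; the child
  term is robust to population stratification, dynastic effects, and
  assortative mating.

All exposure coefficients are reported in SD of the (transformed)
outcome per 5 kg/m^2 of BMI.
"""

from __future__ import annotations

import pandas as pd

from .regression import (EstimateRecord, IVResults, LinearModel, ModelSpec,
                         RegressionResults, TrioIVModel)

__all__ = [
    "classic_spec", "within_family_spec", "ols_spec",
    "fit_ols", "fit_2sls", "classic_mr", "within_family_mr",
    "conditional_first_stage", "quintile_ols",
]

_EXPOSURES = ("child_bmi", "mother_bmi", "father_bmi")
_INSTRUMENTS = ("pgs_child", "pgs_mother", "pgs_father")
_DEFAULT_COVARIATES = ("child_sex", "birth_year")


def ols_spec(outcome: str, covariates=_DEFAULT_COVARIATES, cluster="cluster_id",
             transform="standardize") -> ModelSpec:
    return ModelSpec(outcome=outcome, exposures=_EXPOSURES, instruments=(),
                     covariates=tuple(covariates), cluster=cluster,
                     transform=transform)


def classic_spec(outcome: str, covariates=_DEFAULT_COVARIATES, cluster="cluster_id",
                 transform="standardize") -> ModelSpec:
    return ModelSpec(outcome=outcome, exposures=("child_bmi",),
                     instruments=("pgs_child",), covariates=tuple(covariates),
                     cluster=cluster, transform=transform)


def within_family_spec(outcome: str, covariates=_DEFAULT_COVARIATES,
                       cluster="cluster_id", transform="standardize") -> ModelSpec:
    return ModelSpec(outcome=outcome, exposures=_EXPOSURES,
                     instruments=_INSTRUMENTS, covariates=tuple(covariates),
                     cluster=cluster, transform=transform)


def fit_ols(spec: ModelSpec, cohort: pd.DataFrame) -> list[EstimateRecord]:
    """OLS estimates for every exposure term (robust / cluster-robust SEs)."""
    res = LinearModel.from_spec(cohort, spec).fit()
    res.estimator = "ols"
    return res.records(terms=spec.exposures, outcome=spec.outcome,
                       transform=spec.transform)


def fit_2sls(spec: ModelSpec, cohort: pd.DataFrame,
             estimator_label: str | None = None) -> list[EstimateRecord]:
    """2SLS estimates for every exposure with conditional diagnostics."""
    res = TrioIVModel.from_spec(cohort, spec).fit()
    res.estimator = estimator_label or (
        "within_family_mr" if len(spec.exposures) > 1 else "classic_mr")
    return res.records(terms=spec.exposures, outcome=spec.outcome,
                       transform=spec.transform)


def classic_mr(cohort: pd.DataFrame, outcome: str, covariates=_DEFAULT_COVARIATES,
               cluster: str | None = "cluster_id",
               transform: str = "standardize") -> EstimateRecord:
    """Child-BMI effect with the child's PGS as the sole instrument."""
    spec = classic_spec(outcome, covariates, cluster, transform)
    return fit_2sls(spec, cohort, estimator_label="classic_mr")[0]


def within_family_mr(cohort: pd.DataFrame, outcome: str,
                     covariates=_DEFAULT_COVARIATES,
                     cluster: str | None = "cluster_id",
                     transform: str = "standardize") -> dict[str, EstimateRecord]:
    """Child, mother, and father BMI effects from the trio-instrument model."""
    spec = within_family_spec(outcome, covariates, cluster, transform)
    recs = fit_2sls(spec, cohort, estimator_label="within_family_mr")
    return {r.term.split("_")[0]: r for r in recs}


def conditional_first_stage(spec: ModelSpec, cohort: pd.DataFrame) -> pd.DataFrame:
    """Conditional F and partial R^2 per instrumented exposure."""
    res = TrioIVModel.from_spec(cohort, spec).fit()
    return pd.DataFrame({"conditional_F": res.conditional_F,
                         "conditional_R2": res.conditional_R2})


def quintile_ols(cohort: pd.DataFrame, outcome: str, exposure: str = "child_bmi",
                 covariates=_DEFAULT_COVARIATES, cluster="cluster_id",
                 transform: str = "standardize") -> list[EstimateRecord]:
    """Nonlinearity check: outcome on exposure-quintile indicators
    (lowest quintile is the reference)."""
    df = cohort.copy()
    q = pd.qcut(df[exposure], 5, labels=False)
    terms = []
    for lvl in range(1, 5):
        col = f"{exposure}_q{lvl + 1}"
        df[col] = (q == lvl).astype(float)
        terms.append(col)
    spec = ModelSpec(outcome=outcome, exposures=tuple(terms), instruments=(),
                     covariates=tuple(covariates), cluster=cluster,
                     transform=transform, exposure_unit=1.0)
    res = LinearModel.from_spec(df, spec).fit()
    res.estimator = "ols_quintiles"
    return res.records(terms=terms, outcome=outcome, transform=transform,
                       scale="indicator")
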