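"""From-scratch linear and instrumental-variable estimation.

Implements ordinary least squares and two-stage least squares with
heteroskedasticity-robust (HC1-style) and cluster-robust (CR1-style)
sandwich covariances, Sanderson–Windmeijer-style conditional
first-stage diagnostics for multivariable IV models, and the small
estimate-level utilities (z tests of difference, unit rescaling) used
when comparing estimators.

The estimators are authored here deliberately rather than delegated:
the package's purpose is a transparent, testable implementation of the
trio-instrument within-family MR design, and the IV covariance must
use structural residuals (y - X b with the *observed* exposures), a
detail that matters for correctness and is easy to get wrong.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EstimateRecord", "ModelSpec", "RegressionResults", "IVResults",
    "LinearModel", "TrioIVModel", "z_difference", "rescale_effect",
    "RankDeficientError", "IdentificationError", "WeakInstrumentWarning",
]

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054  # normal 97.5% quantile; normal-theory CIs throughout


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; message names collinear columns."""


class IdentificationError(ValueError):
    """Fewer instruments than endogenous regressors."""


class WeakInstrumentWarning(UserWarning):
    """Conditional first-stage F below the warning threshold."""


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class EstimateRecord:
    """One fitted coefficient with normal-theory inference.

    ``beta`` is reported in SD of the (transformed) outcome per 5 kg/m^2
    of BMI for exposure terms unless ``scale`` says otherwise.
    """

    term: str
    beta: float
    se: float
    estimator: str
    n: int
    outcome: str = "outcome"
    transform: str = "standardize"
    scale: str = "per5kgm2"
    cond_F: float | None = None
    cond_R2: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z975 * self.se

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        z = self.beta / self.se
        return float(2.0 * stats.norm.sf(abs(z)))

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome, "estimator": self.estimator, "term": self.term,
            "beta": self.beta, "se": self.se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p, "n": self.n,
            "cond_F": self.cond_F, "cond_R2": self.cond_R2,
            "transform": self.transform, "scale": self.scale,
        }


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression / IV model.

    ``exposures`` and ``instruments`` are column names in the cohort
    frame; within-family specs carry three of each (child, mother,
    father BMI instrumented by the three polygenic scores), classic
    specs one of each.  Exposure columns are divided by
    ``exposure_unit`` (kg/m^2) before fitting so coefficients read as
    SD outcome per 5 kg/m^2.
    """

    outcome: str
    exposures: tuple[str, ...]
    instruments: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    cluster: str | None = None
    transform: str = "standardize"  # standardize | log1p | none
    exposure_unit: float = 5.0

    def __post_init__(self):
        if self.instruments and len(self.instruments) < len(self.exposures):
            raise IdentificationError(
                f"{len(self.instruments)} instruments cannot identify "
                f"{len(self.exposures)} exposures"
            )
        if self.transform not in ("standardize", "log1p", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


def _transform_outcome(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log1p":
        y = np.log1p(y)
    if transform in ("standardize", "log1p"):
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValueError("outcome has zero variance; cannot standardize")
        y = (y - y.mean()) / sd
    return y


def _design_from_frame(df: pd.DataFrame, spec: ModelSpec):
    """Complete-case arrays (y, X_expo, Z_inst, C_covars, cluster ids)."""
    cols = [spec.outcome, *spec.exposures, *spec.instruments, *spec.covariates]
    if spec.cluster:
        cols.append(spec.cluster)
    sub = df[cols]
    mask = sub.notna().all(axis=1).to_numpy()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("complete-case analysis: dropped %d of %d rows", dropped, len(df))
    sub = sub.loc[mask]
    y = _transform_outcome(sub[spec.outcome].to_numpy(float), spec.transform)
    X = sub[list(spec.exposures)].to_numpy(float) / spec.exposure_unit
    Z = sub[list(spec.instruments)].to_numpy(float) if spec.instruments else None
    C = sub[list(spec.covariates)].to_numpy(float) if spec.covariates else np.empty((len(sub), 0))
    g = sub[spec.cluster].to_numpy() if spec.cluster else None
    return y, X, Z, C, g


# ---------------------------------------------------------------------------
# linear algebra helpers


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficientError("more columns than rows in design")
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (d.max() if d.size else 1.0)
    bad = [names[i] for i in np.where(d <= tol)[0]]
    if bad:
        raise RankDeficientError(f"design is rank deficient; collinear columns: {bad}")


def _sandwich(design: np.ndarray, resid: np.ndarray, cluster) -> np.ndarray:
    """HC1- or CR1-style sandwich covariance for LS-type estimators.

    ``design`` is the matrix whose cross-product forms the bread (for
    2SLS, the instrument-projected regressors).
    """
    n, p = design.shape
    bread = np.linalg.inv(design.T @ design)
    if cluster is None:
        meat = (design * resid[:, None] ** 2).T @ design
        factor = n / (n - p)
    else:
        codes, _ = pd.factorize(cluster)
        G = codes.max() + 1
        scores = np.zeros((G, p))
        u = design * resid[:, None]
        np.add.at(scores, codes, u)
        meat = scores.T @ scores
        factor = (G / (G - 1)) * ((n - 1) / (n - p))
    return factor * bread @ meat @ bread


# ---------------------------------------------------------------------------
# OLS


class _ResultsBase:
    """Shared accessors for fitted-model results."""

    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    model_names: list[str]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.tvalues.to_numpy())),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"ci_low": self.params - q * self.bse, "ci_high": self.params + q * self.bse}
        )

    def summary(self) -> str:
        tab = pd.DataFrame({
            "coef": self.params, "se": self.bse, "z": self.tvalues,
            "P>|z|": self.pvalues,
        }).join(self.conf_int())
        head = f"{type(self).__name__}  n={self.nobs}"
        return head + "\n" + tab.to_string(float_format=lambda v: f"{v: .4f}")


@dataclass
class RegressionResults(_ResultsBase):
    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    resid: np.ndarray
    model_names: list[str]
    estimator: str = "ols"

    def records(self, terms=None, outcome: str = "outcome",
                transform: str = "standardize", n: int | None = None,
                **extra) -> list[EstimateRecord]:
        terms = list(terms) if terms is not None else list(self.params.index)
        return [
            EstimateRecord(
                term=t, beta=float(self.params[t]), se=float(self.bse[t]),
                estimator=self.estimator, n=n or self.nobs, outcome=outcome,
                transform=transform, **extra,
            )
            for t in terms
        ]


class LinearModel:
    """OLS with robust (HC1) or cluster-robust (CR1) covariance.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) regressors *without* a constant (added automatically
        unless ``add_const=False``)
    names : regressor names
    cluster : optional (n,) cluster labels for CR1 errors
    """

    def __init__(self, y, X, names=None, cluster=None, add_const=True):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
        if add_const:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["const", *names]
        self.y, self.X, self.names, self.cluster = y, X, names, cluster

    @classmethod
    def from_spec(cls, df: pd.DataFrame, spec: ModelSpec) -> "LinearModel":
        y, X, _, C, g = _design_from_frame(df, spec)
        design = np.column_stack([X, C])
        names = [*spec.exposures, *spec.covariates]
        return cls(y, design, names=names, cluster=g)

    def fit(self) -> RegressionResults:
        _check_rank(self.X, self.names)
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        cov = _sandwich(self.X, resid, self.cluster)
        return RegressionResults(
            params=pd.Series(beta, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            nobs=len(self.y), resid=resid, model_names=self.names,
        )


# ---------------------------------------------------------------------------
# 2SLS


@dataclass
class IVResults(_ResultsBase):
    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    resid: np.ndarray
    model_names: list[str]
    conditional_F: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    conditional_R2: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    estimator: str = "2sls"

    def records(self, terms=None, outcome: str = "outcome",
                transform: str = "standardize", n: int | None = None,
                **extra) -> list[EstimateRecord]:
        terms = list(terms) if terms is not None else list(self.params.index)
        out = []
        for t in terms:
            out.append(EstimateRecord(
                term=t, beta=float(self.params[t]), se=float(self.bse[t]),
                estimator=self.estimator, n=n or self.nobs, outcome=outcome,
                transform=transform,
                cond_F=float(self.conditional_F[t]) if t in self.conditional_F else None,
                cond_R2=float(self.conditional_R2[t]) if t in self.conditional_R2 else None,
                **extra,
            ))
        return out


class TrioIVModel:
    """Two-stage least squares with excluded instruments.

    The classic-MR design uses one endogenous exposure (child BMI) and
    one excluded instrument (child PGS); the within-family design uses
    three exposures (child, mother, father BMI) and three instruments
    (the trio's polygenic scores).  Covariates enter both stages.

    Covariance uses structural residuals ``y - X b`` with the observed
    exposures, sandwiched through the projected regressors, with an
    HC1/CR1 degrees-of-freedom correction.
    """

    def __init__(self, y, endog, instruments, exog=None,
                 endog_names=None, exog_names=None, cluster=None, add_const=True):
        y = np.asarray(y, float)
        endog = np.asarray(endog, float)
        if endog.ndim == 1:
            endog = endog[:, None]
        instruments = np.asarray(instruments, float)
        if instruments.ndim == 1:
            instruments = instruments[:, None]
        if instruments.shape[1] < endog.shape[1]:
            raise IdentificationError(
                f"{instruments.shape[1]} instruments cannot identify "
                f"{endog.shape[1]} exposures"
            )
        exog = np.empty((len(y), 0)) if exog is None else np.asarray(exog, float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.endog_names = (list(endog_names) if endog_names is not None
                            else [f"x{i}" for i in range(endog.shape[1])])
        exog_names = (list(exog_names) if exog_names is not None
                      else [f"c{i}" for i in range(exog.shape[1])])
        if add_const:
            exog = np.column_stack([np.ones(len(y)), exog])
            exog_names = ["const", *exog_names]
        self.y, self.X_endog, self.Z_excl, self.exog = y, endog, instruments, exog
        self.exog_names = exog_names
        self.cluster = cluster

    @classmethod
    def from_spec(cls, df: pd.DataFrame, spec: ModelSpec) -> "TrioIVModel":
        y, X, Z, C, g = _design_from_frame(df, spec)
        return cls(y, X, Z, exog=C, endog_names=list(spec.exposures),
                   exog_names=list(spec.covariates), cluster=g)

    # -- estimation ----------------------------------------------------

    def fit(self, weak_f_threshold: float = 1.0) -> IVResults:
        y = self.y
        X = np.column_stack([self.X_endog, self.exog])
        names = [*self.endog_names, *self.exog_names]
        Z = np.column_stack([self.Z_excl, self.exog])
        _check_rank(Z, [f"z{i}" for i in range(self.Z_excl.shape[1])] + self.exog_names)
        _check_rank(X, names)
        # first stage: project regressors on the full instrument set
        coef_fs, *_ = np.linalg.lstsq(Z, X, rcond=None)
        Xhat = Z @ coef_fs
        beta, *_ = np.linalg.lstsq(Xhat, y, rcond=None)
        resid = y - X @ beta  # structural residuals with observed exposures
        cov = _sandwich(Xhat, resid, self.cluster)
        condF, condR2 = self._conditional_first_stage()
        res = IVResults(
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            nobs=len(y), resid=resid, model_names=names,
            conditional_F=pd.Series(condF, index=self.endog_names),
            conditional_R2=pd.Series(condR2, index=self.endog_names),
        )
        weakest = res.conditional_F.min()
        if np.isfinite(weakest) and weakest < weak_f_threshold:
            warnings.warn(
                f"weak instruments: smallest conditional F = {weakest:.3g}",
                WeakInstrumentWarning, stacklevel=2,
            )
        return res

    def _conditional_first_stage(self):
        """Sanderson–Windmeijer-style conditional F and partial R^2.

        For exposure j: predict the *other* exposures from the full
        instrument set, residualize exposure j on those predictions and
        the covariates, then F-test the excluded instruments in a
        regression of that residual on the full instrument set.  The
        numerator degrees of freedom are k - (m - 1) (instruments minus
        other exposures); with a single exposure this is the ordinary
        first-stage F.  Covariates are conditioned on in every stage.
        """
        y_unused, Xe, Zx, C = self.y, self.X_endog, self.Z_excl, self.exog
        n, m = Xe.shape
        k = Zx.shape[1]
        Z = np.column_stack([Zx, C])
        Fs, R2s = [], []
        for j in range(m):
            others = np.delete(Xe, j, axis=1)
            if others.shape[1]:
                co, *_ = np.linalg.lstsq(Z, others, rcond=None)
                others_hat = Z @ co
                base = np.column_stack([others_hat, C])
            else:
                base = C
            cb, *_ = np.linalg.lstsq(base, Xe[:, j], rcond=None) if base.shape[1] else (np.zeros(0),)
            r = Xe[:, j] - (base @ cb if base.shape[1] else 0.0)
            # restricted: covariates only; full: covariates + excluded instruments
            if C.shape[1]:
                c0, *_ = np.linalg.lstsq(C, r, rcond=None)
                rss0 = float(np.sum((r - C @ c0) ** 2))
            else:
                rss0 = float(np.sum(r**2))
            c1, *_ = np.linalg.lstsq(Z, r, rcond=None)
            rss1 = float(np.sum((r - Z @ c1) ** 2))
            df1 = k - (m - 1)
            df2 = n - Z.shape[1] - (0 if C.shape[1] else 1)
            if rss1 <= 0 or df1 <= 0 or df2 <= 0:
                raise ValueError("degenerate residual variance in conditional first stage")
            Fs.append(((rss0 - rss1) / df1) / (rss1 / df2))
            R2s.append((rss0 - rss1) / rss0 if rss0 > 0 else np.nan)
        return Fs, R2s


# ---------------------------------------------------------------------------
# estimate-level utilities


def z_difference(a: EstimateRecord, b: EstimateRecord) -> dict:
    """Two-sided z test comparing two estimates of the same term.

    Treats the estimates as independent (they share data, so the p-value
    is approximate — the convention when comparing classic and
    within-family MR coefficients).
    """
    var = a.se**2 + b.se**2
    if var <= 0:
        raise ValueError("zero combined variance in z_difference")
    z = (a.beta - b.beta) / np.sqrt(var)
    return {"z": float(z), "p": float(2.0 * stats.norm.sf(abs(z)))}


_SCALE_UNITS = {"per5kgm2": 5.0, "per1kgm2": 1.0}


def rescale_effect(record: EstimateRecord, bmi_sd: float | None = None,
                   target: str = "per1kgm2") -> EstimateRecord:
    """Rescale a BMI-exposure estimate between per-5 kg/m^2, per-1 kg/m^2,
    and per-SD-of-BMI units; SE and CI scale with the point estimate."""
    src = record.scale
    if src not in _SCALE_UNITS and src != "per_sd_bmi":
        raise ValueError(f"unknown source scaling {src!r}")
    if target not in _SCALE_UNITS and target != "per_sd_bmi":
        raise ValueError(f"unknown target scaling {target!r}")
    if src == target:
        return record
    # convert to per-1 kg/m^2 first
    if src == "per_sd_bmi":
        if bmi_sd is None:
            raise ValueError("bmi_sd required to rescale from per_sd_bmi")
        per1 = 1.0 / bmi_sd
    else:
        per1 = 1.0 / _SCALE_UNITS[src]
    if target == "per_sd_bmi":
        if bmi_sd is None:
            raise ValueError("bmi_sd required to rescale to per_sd_bmi")
        factor = per1 * bmi_sd
    else:
        factor = per1 * _SCALE_UNITS[target]
    return replace(record, beta=record.beta * factor, se=record.se * factor,
                   scale=target)
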