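"""Polygenic score construction and phenotype cleaning.

Covers the scoring pipeline applied before estimation: greedy LD
clumping of GWAS weight tables (p-value ordered, squared-correlation
threshold within a physical window), allele-aligned dosage weighting,
principal components of ancestry from the standardized dosage matrix,
the 4-SD anthropometric outlier rule, and prorated symptom-scale
scores requiring at least 80% item completeness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "read_weight_table", "write_weight_table", "clump", "build_pgs",
    "ScoreVector", "ancestry_pcs", "clean_anthropometrics", "prorate_scale",
]

logger = logging.getLogger(__name__)

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WEIGHT_COLUMNS = ["snp_id", "chromosome", "position", "effect_allele",
                  "other_allele", "beta", "p_value"]


def _validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table lacks columns {missing}")
    if weights["snp_id"].duplicated().any():
        dup = weights.loc[weights["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id in weight table: {dup}")
    bad = ~weights["effect_allele"].isin(_VALID_ALLELES) | ~weights["other_allele"].isin(_VALID_ALLELES)
    if bad.any():
        raise ValueError("weight table alleles must be one of A/C/G/T")
    p = weights["p_value"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p_value must lie in (0, 1]")
    return weights


def read_weight_table(path) -> pd.DataFrame:
    """Tab-delimited GWAS weight table with a header row."""
    return _validate_weights(pd.read_csv(path, sep="\t"))


def write_weight_table(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clumping


def clump(weights: pd.DataFrame, ld_ref: GenotypeMatrix,
          r2_threshold: float = 0.01, window_kb: float = 10_000.0,
          p_threshold: float = 5e-8) -> pd.DataFrame:
    """Greedy p-value-ordered selection of approximately independent SNPs.

    SNPs are taken in ascending p-value order; a candidate is accepted
    iff its p-value passes ``p_threshold`` and its squared dosage
    correlation in ``ld_ref`` with every already-accepted SNP on the
    same chromosome within ``window_kb`` is below ``r2_threshold``.
    Weight-table rows for SNPs absent from the LD reference are dropped
    with a logged count; monomorphic reference SNPs are treated as
    uncorrelated (r^2 = 0) with a logged note.

    The reported clumping threshold in the source protocol is printed
    as "r = 0.01" where standard tooling thresholds r^2; this function
    thresholds r^2 and exposes the value as an argument.
    """
    weights = _validate_weights(weights)
    ref_index = {s: i for i, s in enumerate(ld_ref.snps["snp_id"])}
    present = weights["snp_id"].isin(ref_index).to_numpy()
    if (~present).sum():
        logger.info("clump: %d weight-table SNPs absent from LD reference dropped",
                    int((~present).sum()))
    w = weights.loc[present].sort_values(["p_value", "snp_id"], kind="stable")
    w = w[w["p_value"] < p_threshold]
    if w.empty:
        logger.warning("clump: no SNPs pass p < %g; returning empty table", p_threshold)
        return w.reset_index(drop=True)

    dos = ld_ref.dosages.astype(float)
    sd = dos.std(axis=0, ddof=1)
    accepted: list[int] = []  # row positions in w
    acc_cols: list[int] = []  # reference column indices
    chrom = ld_ref.snps["chrom"].to_numpy()
    pos = ld_ref.snps["pos"].to_numpy()
    window_bp = window_kb * 1000.0
    for row_i, snp in enumerate(w["snp_id"].to_numpy()):
        j = ref_index[snp]
        ok = True
        for k in acc_cols:
            if chrom[k] != chrom[j] or abs(pos[k] - pos[j]) > window_bp:
                continue
            if sd[j] == 0 or sd[k] == 0:
                logger.info("clump: monomorphic SNP treated as r^2=0")
                continue
            r = np.corrcoef(dos[:, j], dos[:, k])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(row_i)
            acc_cols.append(j)
    return w.iloc[accepted].reset_index(drop=True)


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class ScoreVector:
    """Per-individual polygenic score with provenance metadata."""

    scores: pd.Series
    n_snps_used: int
    provenance: str = ""

    def to_csv(self, path) -> None:
        self.scores.rename("score").to_csv(path, index_label="id")


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def build_pgs(genotypes: GenotypeMatrix, weights: pd.DataFrame,
              provenance: str = "") -> ScoreVector:
    """Allele-aligned weighted dosage sum.

    Per individual, sum over weight-table SNPs of aligned dosage times
    beta, where the aligned dosage counts the GWAS effect allele
    (flipped to 2 - d when the genotype file counts the other allele).
    Strand-ambiguous (A/T, C/G) SNPs and SNPs whose alleles cannot be
    reconciled by flipping are dropped with a logged count; missing
    dosages are mean-imputed per SNP.
    """
    weights = _validate_weights(weights)
    ref = genotypes.snps.set_index("snp_id")
    n = len(genotypes.ids)
    total = np.zeros(n)
    used = dropped_pal = dropped_mismatch = dropped_absent = 0
    for row in weights.itertuples(index=False):
        if row.snp_id not in ref.index:
            dropped_absent += 1
            continue
        if _is_palindromic(row.effect_allele, row.other_allele):
            dropped_pal += 1
            continue
        g = ref.loc[row.snp_id]
        d = genotypes.dosages[:, ref.index.get_loc(row.snp_id)].astype(float)
        if np.isnan(d).any():
            fill = np.nanmean(d)
            d = np.where(np.isnan(d), fill, d)
        if g["effect_allele"] == row.effect_allele and g["other_allele"] == row.other_allele:
            aligned = d
        elif g["effect_allele"] == row.other_allele and g["other_allele"] == row.effect_allele:
            aligned = 2.0 - d
        else:
            dropped_mismatch += 1
            continue
        total += aligned * row.beta
        used += 1
    if dropped_pal or dropped_mismatch or dropped_absent:
        logger.info("build_pgs: dropped %d palindromic, %d allele-mismatch, "
                    "%d absent SNPs", dropped_pal, dropped_mismatch, dropped_absent)
    scores = pd.Series(total, index=pd.Index(genotypes.ids, name="id"))
    if not np.isfinite(total).all():
        raise ValueError("non-finite polygenic score produced")
    return ScoreVector(scores=scores, n_snps_used=used, provenance=provenance)


# ---------------------------------------------------------------------------
# ancestry components


def ancestry_pcs(genotypes: GenotypeMatrix, k: int = 20) -> pd.DataFrame:
    """Top-k principal components of ancestry.

    Left singular vectors of the column-standardized dosage matrix
    (monomorphic SNPs dropped), rescaled to unit variance.  The sign of
    each component is fixed by making its largest-magnitude SNP loading
    positive, so repeated runs are deterministic.
    """
    dos = genotypes.dosages.astype(float)
    sd = dos.std(axis=0, ddof=1)
    keep = sd > 0
    dos = (dos[:, keep] - dos[:, keep].mean(axis=0)) / sd[keep]
    max_k = min(dos.shape) - 1
    if k > max_k:
        raise ValueError(f"k={k} exceeds achievable rank; at most {max_k} components")
    u, s, vt = np.linalg.svd(dos, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign convention via the dominant loading
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    pcs = u / u.std(axis=0, ddof=1)
    return pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(k)],
                        index=pd.Index(genotypes.ids, name="id"))


# ---------------------------------------------------------------------------
# anthropometrics


def clean_anthropometrics(height: pd.Series, weight: pd.Series,
                          sd_limit: float = 4.0) -> pd.DataFrame:
    """BMI (kg/m^2) from height (m) and weight (kg) with outlier coding.

    Values more than ``sd_limit`` standard deviations from the variable
    mean are coded missing in a single pass using the all-sample
    mean/SD; non-positive values are coded missing with a log entry.
    BMI is computed for complete pairs only.
    """
    h = pd.Series(height, dtype=float).copy()
    w = pd.Series(weight, dtype=float).copy()
    for s, name in ((h, "height"), (w, "weight")):
        nonpos = (s <= 0) & s.notna()
        if nonpos.any():
            logger.info("clean_anthropometrics: %d non-positive %s values coded missing",
                        int(nonpos.sum()), name)
            s[nonpos] = np.nan
        mu, sd = s.mean(), s.std(ddof=1)
        if sd > 0:
            out = (s - mu).abs() > sd_limit * sd
            if out.any():
                logger.info("clean_anthropometrics: %d %s outliers (> %g SD) coded missing",
                            int(out.sum()), name, sd_limit)
            s[out] = np.nan
    bmi = w / h**2
    return pd.DataFrame({"height": h, "weight": w, "bmi": bmi})


# ---------------------------------------------------------------------------
# symptom scales


def prorate_scale(item_responses: pd.DataFrame, n_items: int | None = None,
                  min_prop: float = 0.8, max_category: int | None = None) -> pd.Series:
    """Prorated questionnaire totals.

    An individual's score is the sum of answered items rescaled by
    ``n_items / answered`` when the answered fraction reaches
    ``min_prop`` (threshold = ceiling(min_prop * n_items) answered
    items, so 11 of 13 are required at 80%); otherwise missing.
    """
    items = item_responses.astype(float)
    n_items = n_items if n_items is not None else items.shape[1]
    vals = items.to_numpy()
    answered_mask = ~np.isnan(vals)
    filled = np.where(answered_mask, vals, 0.0)
    neg_cols = (filled < 0).any(axis=0)
    if neg_cols.any():
        raise ValueError(f"negative item response in {items.columns[np.argmax(neg_cols)]!r}")
    if max_category is not None:
        over = (filled > max_category).any(axis=0)
        if over.any():
            raise ValueError(
                f"item {items.columns[np.argmax(over)]!r} exceeds category "
                f"range 0..{max_category}"
            )
    answered = answered_mask.sum(axis=1)
    need = math.ceil(min_prop * n_items)
    sums = np.nansum(vals, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(answered >= need, sums * n_items / answered, np.nan)
    return pd.Series(score, index=item_responses.index)
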