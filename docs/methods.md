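# Methods

This note documents the generative model, the estimators, the
numerical choices, and the limits of what the simulation-based tests
can show.

## Generative model

One simulated family is a mother–father–child trio.  Writing `G_i` for
the standardized true polygenic score of member `i` and `S` for the
family's subpopulation label:

```
BMI_i   = mean_i + sd_i * ( sqrt(r2_i) G_i + shift_S + c C_fam + e_i )
y       = beta_c BMI_c/5 + alpha_m BMI_m/5 + alpha_f BMI_f/5
          + theta G_c + shift'_S + c' C_fam + eps
```

* `C_fam ~ N(0,1)` is a family-level confounder shared by all three
  members (the "aspects of the family environment" channel); its
  loading `c` (SD units, default 0.2) applies to both BMI and the
  outcome unless overridden per outcome.
* `shift_S` are per-subpopulation mean shifts, evenly spaced in
  `[-amplitude, +amplitude]` and centred; together with
  Balding–Nichols allele-frequency divergence (`fst`) they create the
  gene–environment correlation that biases classic MR.
* residual variances are solved analytically so that each BMI has
  exactly its configured variance and the outcome has unit variance
  under the null configuration; a configuration whose variance shares
  exceed 1 raises a configuration error naming the role.
* `theta` is a direct (horizontally pleiotropic) effect of the child's
  aggregate score on the outcome.

The structural equations above are this package's reconstruction of
the trio design's bias structure (stratification, dynastic effects,
assortative mating) from its public description; they are not a copy
of any proprietary model specification.

**Genotypes.**  Founder (parental) genotypes use the Balding–Nichols
construction: ancestral MAF uniform on `maf_range`, subpopulation
frequency `~ Beta(p(1-F)/F, (1-p)(1-F)/F)`.  Within-block LD is
induced by thresholding an AR(1) Gaussian copula (latent correlation
`ld_rho`, block size `ld_block_size`) per haplotype; dosage = two
independent haplotypes, so Hardy–Weinberg holds within subpopulation.
Blocks are placed 20 Mb apart so LD (and the 10,000-kb clumping
window) never spans blocks.  Children receive per-SNP independent
Bernoulli transmissions `Bern(d_m/2) + Bern(d_f/2)`; this is unphased
and destroys parental LD in child haplotypes, which is acceptable
because clumping only ever consumes founder-generation LD.

**Fast score-level path (`n_snps = 0`).**  Parents' true scores are
standard normal; the child score is mid-parent plus segregation noise
of variance ½, so `corr(G_c, G_parent) = ½` and `var(G_c) = 1` under
random mating.  The true score doubles as the instrument.  This path
is exact for every property that does not touch individual SNPs and
is used for replicate-heavy checks (precision ratios, type-I error,
power).  It supports a single subpopulation only; stratification
scenarios run SNP-level.

**Assortative mating.**  Spouses are paired by Gaussian-copula rank
matching: each parent receives a latent mating score
`sum_t a_t z_t + noise` over rank-normalized traits, and mothers and
fathers are paired by latent rank within subpopulation (endogamy).
Realized cross-correlations converge to `a_t b_s`, so the target
matrix must be rank-1; non-factorizable targets raise with the
achievable bound.  Because the family confounder (and, under
endogamy, subpopulation shifts) are added to both spouses after
pairing, the within-pairing target is deflated analytically
(`r_pre = (r - s)/(1 - s)` with `s` the shared variance fraction) so
the realized spousal BMI correlation matches the configured value;
the default 0.23 is realized within ±0.01 at n = 40,949.

**Defaults.**  The default configuration emulates the analysed
cohort: 40,949 trios; BMI 16.3 (SD 2.0) for children, 24.0 (4.1) for
mothers, 25.9 (3.2) for fathers; PGS R² 1.7% / 3.2% / 3.0%; spousal
BMI correlation 0.23; homogeneous ancestry (post-QC European-ancestry
samples carry little stratification, so `n_subpops=1, fst=0` by
default and stratification is an explicit scenario).  The
`moba_like()` constructor adds the three symptom scales (13-item 0–2
depressive, 5-item 0–2 anxiety, 18-item 0–3 ADHD analogues; printed
ranges 0–26, 0–10, 0–54) with the within-family point estimates as
causal defaults (0.26 with a 0.11 maternal dynastic effect; null;
0.36).  Ordinal items are generated from the outcome liability by a
graded-threshold model (item loading 0.7, exceedance probabilities
0.12/0.03/0.01) chosen to give the zero-heavy distributions typical of
parent-reported symptom scales.

**Scenario constructors and the closed-form dynastic oracle.**  The
`dynastic()` scenario is parameterized with exchangeable roles (equal
PGS R² and BMI SD for child, mother, father) because the closed-form
probability limit of classic MR,
`beta_c + (alpha_m + alpha_f)/2`, holds exactly when the score→BMI
covariance is equal across roles; with role-specific R² and SD the
bias generalizes to
`beta_c + (alpha_m k_m + alpha_f k_f)/2, k_i = sqrt(r2_i) sd_i / (sqrt(r2_c) sd_c)`.
The tests target the exchangeable form.

## Estimators

* **OLS** (`LinearModel`): least squares with HC1 heteroskedasticity-
  robust or CR1 cluster-robust sandwich covariance (degrees-of-freedom
  factors `n/(n-p)` and `G/(G-1)·(n-1)/(n-p)`), matching the common
  commercial implementations; verified against statsmodels in tests.
* **2SLS** (`TrioIVModel`): regressors projected on the full
  instrument set (excluded instruments + covariates); the covariance
  uses *structural* residuals `y - X b` with the observed exposures,
  sandwiched through the projected regressors.  Covariates enter both
  stages.  Exposures are scaled per 5 kg/m² before fitting; outcomes
  may be left raw, standardized, or log(score+1)-then-standardized.
* **Conditional first-stage diagnostics**: Sanderson–Windmeijer-style.
  For exposure j, the other exposures are replaced by their
  instrument-predicted values, exposure j is residualized on those
  predictions and the covariates, and the excluded instruments are
  F-tested in a regression of that residual (numerator df
  `k - (m - 1)`).  The reported conditional R² is the partial R² of
  that final regression.  With one exposure this reduces to the
  ordinary first-stage F (`F = R²/(1-R²)·(n-2)` with a single
  instrument).  Whether the original analyses conditioned covariates
  before or after instrument projection is not public; this package
  conditions on covariates in every stage and documents that choice.
  Under random mating the child's conditional R² is half its marginal
  R² — conditioning on the parents halves usable instrument
  variance — which is why within-family SEs are √2 larger and the
  relative precision is √½ ≈ 70.7%.
* **Inference**: normal-theory 95% CIs and two-sided p-values
  throughout (at cohort-scale n a t correction is immaterial).  The z
  test of difference `z = (b_a - b_b)/sqrt(se_a² + se_b²)` treats the
  two estimates as independent although they share data; the p-value
  is therefore approximate, and this convention is stated wherever it
  is used.
* **Summary-statistic estimators**: IVW is weighted regression through
  the origin (weights `1/se_out²`) with multiplicative random-effects
  scaling applied when Cochran's Q exceeds `k-1` (Q is computed and
  kept even though it is rarely reported, because the random-effects
  decision needs it); MR-Egger shares the same weighted-LS core with a
  free intercept (equality of the slope with IVW under a constrained
  intercept is exact); the weighted median uses the standard
  cumulative-weight interpolation; the mode-based estimator maximizes
  a normal-kernel weighted density of Wald ratios with bandwidth
  `factor × 0.9 min(sd, IQR/1.349) n^{-1/5}` (grid search refined by
  bounded scalar optimization).  Median/mode SEs are parametric
  bootstraps (default 1,000 replicates, seeded).  Harmonization
  orients exposure betas positive and both betas flip together;
  palindromic (A/T, C/G) SNPs are dropped in scoring, consistent with
  the Egger convention.
* **Complete-case analysis only**: rows with missing model variables
  are dropped with logged counts.  Multiple imputation is out of
  scope; the complete-case flag mirrors the corresponding sensitivity
  analysis.

## Polygenic scoring

Clumping is greedy and p-value-ordered: accept a SNP iff `p <
p_threshold` (default 5×10⁻⁸) and its squared dosage correlation with
every accepted same-chromosome SNP within the window (default
10,000 kb) is below the threshold.  The protocol this mirrors prints
the clumping threshold as "r = 0.01" where standard tooling
thresholds r²; this package thresholds r² = 0.01 and exposes the
value as an argument — a documented divergence in notation, not
substance.  Scoring aligns dosages to the GWAS effect allele (flip to
`2-d` when the counted allele is the other allele), drops
strand-ambiguous SNPs, and mean-imputes missing dosages per SNP —
standard PGS practice.  Anthropometric cleaning applies the 4-SD rule
in a single pass with the all-sample mean/SD (the plain reading of
the rule; no iteration).  Prorated scale scores require
`ceil(0.8 × n_items)` answered items (11 of 13), then rescale the
answered sum by `n_items/answered`.  Ancestry components are the
top-k left singular vectors of the column-standardized dosage matrix,
unit-variance scaled, with signs fixed by the dominant loading.

## Power analysis

`estimate_power` measures the rejection rate of the child term over
seeded replicate cohorts (fast path); `minimum_detectable_effect`
inverts it by bisection using common random numbers (the same
replicate seeds at every effect size, making the estimated power
monotone in the effect along the bisection path), and reports the
analytic approximation `(z_{1-alpha/2} + z_{power}) × SE ≈ 2.8 × SE`
from 20 pilot null replicates alongside.  The published minimum
detectable effects for this design (0.15/0.22 SD for the adult-BMI
score; 0.12/0.16 for the childhood-body-size score) came from an
unreported simulation whose generative parameters are not public and
are not numerically consistent with the obvious parameterization of
the real-data SEs; this module therefore reports simulated and
analytic MDEs under its own explicitly logged parameters and makes no
attempt to reproduce those printed values.

## Problem sizes used in the test suite

Replicate-heavy checks run on the fast path at full cohort size
(200 replicates × 40,949 families for the precision ratio and the
dynastic bias limits; 1,500 replicates × 10,000 for type-I error,
where the larger replicate count keeps the binomial Monte-Carlo band
tight relative to a three-estimator comparison; 500 replicates per
power evaluation at n = 10,000).  SNP-level property tests (clumping
oracle, ancestry PCs, stratification scenarios, SNP-outcome
associations) use reduced sizes (hundreds to thousands of families,
tens to hundreds of SNPs), which are ample for their closed-form or
oracle comparisons.

## What passing tests do and do not show

The simulator realizes the bias structures exactly as specified, with
Gaussian noise, linear effects, a rank-1 mating mechanism, and
independent SNPs (LD only within synthetic blocks).  Real cohorts
have non-Gaussian outcomes (the ordinal item generator reproduces the
zero-inflation but analyses here use the continuous liabilities),
realistic LD, phased transmission, participation bias, and
measurement error in reported height/weight — none of which are
emulated.  Passing tests therefore certify the estimators and the
design algebra (bias limits, precision ratios, calibration), not the
substantive conclusions one would draw from any real cohort.

## Known limitations

* Parental (mother/father) terms in the within-family model are not
  protected from biases in earlier generations (grandparental
  genotype is not modelled), matching the design's own caveat.
* The z test of difference ignores the correlation between estimators
  fitted on the same data.
* The mating mechanism cannot realize non-rank-1 spousal target
  matrices, and realized cross-trait targets are approximate at small
  n.
* Sibling clusters are available (`sibship_rate`) for cluster-robust
  SE tests, but extended pedigrees are not modelled.
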