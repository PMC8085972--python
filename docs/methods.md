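# Methods

This note documents the models, defaults and design choices behind
`ihcrisk`, and what the synthetic layers do and do not establish.

## Stain model and phantoms

Pixels mix stains by Beer–Lambert absorbance: with per-stain unit
absorbance vectors *S* (rows: brown chromogen, blue chromogen,
counterstain; columns: R, G, B) and nonnegative concentrations *c*,
the rendered intensity is I_ch = round(255·10^(−(Sᵀc)_ch)) clipped to
[0, 255]. The brown row is the widely published DAB absorbance
direction (0.268, 0.570, 0.776) and the counterstain row is the
standard hematoxylin direction (0.650, 0.704, 0.286). No published
absorbance vector exists for Ferangi Blue; the default
(0.850, 0.500, 0.170, normalised) is a documented package choice made
to absorb mostly red/green (so it appears blue) while sitting ~50°
from DAB, which keeps the 3×3 unmixing well conditioned (condition
number ≈ 11). Users with a calibrated basis can pass their own
`StainBasis`.

Phantom geometry is a union of random disks emulating glandular
regions; background is pure white (OD 0), which makes the 0.08 tissue
threshold meaningful. Positive pixels are a uniformly random subset of
tissue pixels at the requested fraction (brown and blue sets are
disjoint; requesting fractions summing above 1 is an error).
Concentrations are drawn from a normal centred on the requested mean
OD with relative SD 0.15, truncated at ±1.5 SD — so every positive
pixel stays above 0.775× the mean, safely above the 0.15 positivity
threshold whenever the mean OD is ≥ 0.2, and the rendered positive set
coincides exactly with the ground-truth mask. Ground-truth PPEA/AEI are
computed from the realised masks and concentration maps, not from the
request, so recovery tests compare against the truth actually rendered.
One integer seed fully determines a phantom.

What the phantoms do *not* emulate: nuclear/gland morphology, scanner
colour profiles, tissue folds and staining artefacts, and spatially
correlated stain texture. Passing recovery tests therefore shows the
arithmetic of the quantification chain is right, not that it is robust
to real-slide artefacts (the source workflow handled those by manual
annotation, which the `region_mask` argument emulates).

## Quantification conventions

The tissue threshold applies to the *mean* of the three channel ODs;
the source workflow's "overall staining OD" is not defined precisely,
and the channel mean is the common digital-pathology choice. Both
thresholds are strict (>), fixing the boundary case for exact tests.
Positivity is assessed on the deconvolved stain channel rather than
raw colour because the two chromogens overlap spectrally. The
expression score uses the natural log: observed scores around −7 to −4
are consistent with ln of PPEA·AEI products in the 10⁻³–10⁻² range
(log₁₀ would give ≈ −2). Subjects with several annotated regions are
aggregated by pixel pooling (total positive / total tissue;
positive-pixel-weighted AEI) — the only aggregation invariant to how
regions are partitioned. A subject with pooled PPEA = 0 has undefined
expression and is flagged for exclusion downstream.

## Cohort simulator

Defaults are the package's study conditions: n = 10,478 men, 46%
African-American, entry uniform over 1990–2011 with administrative
censoring at the end of 2012, age ~ N(64.5, 7.3²) years, PSA lognormal
(meanlog 1.45, sdlog 0.6 → median ≈ 4.3 ng/ml), inflammation
categories (none / chronic only / chronic and/or acute) with
probabilities (0.392, 0.523, 0.085). Expression scores are bivariate
normal within race with cross-marker correlation 0.39 and race-specific
moments: NF-κB −5.41 ± 1.59 (AA) vs −4.79 ± 1.49 (White); GDF-15
−7.12 ± 1.40 (AA) vs −6.70 ± 1.38 (White) — i.e. both markers lower in
AA men.

Event times are exponential per subject (constant hazard): the simplest
model consistent with incidence-density logic, since no survival model
is fit downstream. The log-hazard is linear in centred covariates with
defaults β_NF-κB = ln 0.85, β_GDF-15 = ln 1.06, β_GDF-15² = 0.05,
β_PSA = 0.02, β_inflammation = (−0.05, −0.10), around a baseline of
0.006 events/person-year (≈ 7% cumulative incidence over the follow-up
window). Marker and PSA terms are centred at their population means so
the baseline hazard is the rate at average covariates. Under
incidence-density sampling the matched-pair odds ratio estimates the
hazard ratio, so these coefficients are the recoverable truth for the
conditional-logistic models. Case-only Gleason grade group and tumour
stage are drawn from the packaged baseline-table frequencies (including
a 21/503 missing-grade rate).

The simulator omits competing risks, screening-intensity dynamics, and
secular trends in diagnosis; parameter-recovery results therefore
validate the estimators under the stated model, not robustness to
those violations.

`simulate_matched_pairs` additionally draws pairs directly from the
conditional model (the case is member 1 with probability
σ(βᵀ(x₁ − x₂))), which is the exact data-generating process the pair
likelihood inverts; it is used to test the estimator in isolation from
the matching machinery.

## Matching

Cases require ≥ 1 year between entry and diagnosis (exactly one year is
eligible, matching the "less than 1 year ineligible" rule). The risk
set for a case at index time t contains every other member cancer-free
at t — censored members need follow-up ≥ t, case members must be
diagnosed strictly after t (a case diagnosed exactly at t is not
cancer-free there) — matching on race and within ±2-year calipers on
age and calendar entry date (the entry caliper is applied to calendar
dates). Later cases may serve as controls for earlier index times, and
controls are sampled with replacement: both definitional for
incidence-density sampling. Cases are processed in ascending diagnosis
date (ties by id) and candidates are sorted by id before the uniform
draw, so output is invariant to cohort row order and fully determined
by the seed.

Quartile cutpoints are estimated per race from the control arm only,
with linear interpolation between order statistics; quartile intervals
are right-closed ((−∞, c₁], (c₁, c₂], (c₂, c₃], (c₃, ∞)). Both the
estimator and the tie rule are conventions fixed for reproducibility;
the source analysis does not state its choices.

## Conditional likelihood and inference

The 1:1 conditional likelihood is implemented as an intercept-free
binary likelihood on within-pair differences — an exact algebraic
identity that also permits independent oracles (grid search, the
McNemar identity OR = n₊/n₋ for binary covariates, and an ordinary
logistic fit with all outcomes 1). Newton–Raphson with step halving
converges when the gradient max-norm < 1e-8 (≤ 50 iterations); the
covariance is the inverse observed information. A covariate with
all-zero differences raises a non-identifiability error naming it;
iterates exceeding |β| = 15 raise a separation error (no Firth
correction is attempted). Likelihood-ratio tests compare nested fits on
the same pairs against χ² with df equal to the parameter difference;
identical models give statistic 0 and p = 1.

Adjusted models carry PSA (untransformed), two inflammation indicators
(none as reference), and both markers; continuous marker ORs are per
unit of ln(PPEA × AEI). Trend models enter the quartile code 1–4 as a
single numeric covariate. Polynomial model search starts from the
adjusted linear model and adds a second- then third-order marker term,
each tested at df = 1 against the previous model, stopping at the first
p ≥ 0.05; polynomial terms are centred at the control-arm marker mean
for numerical stability (centring changes neither the likelihood
ordering nor the LRT). Risk curves report
exp(β_lin·g + β_quad·g²) normalised to 1 at the sample mean of g, with
other covariates held at their means (where they cancel from the
relative risk).

Strata (case aggressiveness: Gleason group ≥ 3 or PSA ≥ 20 or stage
≥ 3; age at entry < 65 vs ≥ 65; time to diagnosis < 3.7 vs ≥ 3.7
years) are defined by the case's attributes and both pair members
inherit them — matched sets cannot be split. Strata with fewer than 10
pairs, or in which a sparse covariate separates, are skipped with a
warning rather than reported.

Unmatched group comparisons (expression by race) use an ordinary
linear model with indicator-coded experimental batch and imaging
platform; adjusted group means weight each nuisance level equally, and
perfect confounding of batch with group is an error.

## Problem sizes and tolerances

The validation studies use: 50 random small designs (n ≤ 20, p ≤ 2)
against a five-round zoomed grid search (final spacing < 1e-4,
comparison tolerance 1e-3); 200 replicates of 500 pairs for bias
(tolerance 0.05 on the log OR) and 95% Wald coverage (accepted range
0.92–0.97); 1000 datasets of 200 pairs for LRT type-I error (accepted
0.03–0.07); 20 noise-free phantoms spanning PPEA 0.05–0.9 (tolerances
0.02 OD on PPEA/AEI, 0.05 on expression, dominated by 8-bit
quantisation); and one 10,000-member cohort for matching validity.
These sizes give stable Monte-Carlo estimates while keeping the whole
suite under a few minutes on one CPU.

## Known limitations

* The default Ferangi Blue vector is synthetic; quantification of real
  slides requires a calibrated basis.
* The exponential hazard has no age or calendar-time trend, so the
  matched design removes less confounding than it would in real data.
* Separation is an error, not a correctable condition; very sparse
  strata are skipped rather than penalised-fit.
* The pipeline does not reproduce the source study's patient-data odds
  ratios — those data are unavailable — only the behaviour of the
  estimators under known truth.
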