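# Methods

This note documents the statistical procedures the package implements, the
choices made where the literature leaves details open, and what the synthetic
data do and do not establish.

## The structural question and the comparison-curve approach

Taxometric procedures ask whether a set of ordinal symptom indicators is
generated by a latent class (taxon plus complement) or by a continuum.
Rather than thresholding curve shapes by eye, the comparison-curve approach
simulates two populations from the empirical data — one forced to be
categorical at an assumed base rate, one dimensional — draws repeated samples
from each, and asks which family of sampled curves the empirical curve
resembles more. The comparison curve fit index is

CCFI = FitDim / (FitDim + FitCat),

where FitDim and FitCat are root-mean-square distances between the empirical
curve and the sampled dimensional and categorical curves. The structural
verdict uses the mean CCFI over MAMBAC, MAXEIG and L-Mode; the profile
variant repeats everything over assumed base rates .025–.975 in steps of
.025 and averages, which avoids committing to a single base-rate estimate
and, under a true taxon, peaks near the true base rate.

## Indicators and suitability

Items are 4-point ordinal responses recoded 1–4 → 0–3; each criterion's two
items are summed into a 0–6 indicator. The internal coding is 0-based so the
calibration targets (indicator means 0.31–0.92 on the 0–6 scale) are
consistent; loaders accept either coding. Putative groups for the
suitability checks come from criterion-count rules (DSM-5: 5 of 9; ICD-11:
4 of 4), where a criterion counts as met when its indicator is ≥ 4, i.e.
both items at least "agree somewhat" — the source instruments do not fix
this cut, so it is a configurable default chosen as the strictest symmetric
reading. Suitability thresholds follow taxometric practice: every
indicator's pooled-SD Cohen's *d* between the putative groups > 1.25,
full-sample mean pairwise Pearson *r* > .30, and mean within-group r ≤ .30
in both groups. Correlations are Pearson on the indicator sums; polychoric
variants are out of scope.

## Curve procedures

All procedures operate in case-rank space along a sorting ("input")
indicator; ordinal data produce heavy ties, so tie order is randomized per
replication (default 10) and curves averaged. Reported x coordinates are
1-based ranks, which makes curves from equal-n samples directly comparable
without interpolation.

* **MAMBAC** — 50 cuts evenly spaced in rank space with 25 cases beyond each
  extreme cut; y = mean(output above cut) − mean(output at/below cut); one
  curve per ordered indicator pair, plus the pointwise panel mean.
* **MAXEIG** — 50 windows at 90% overlap tiling the rank range with equal
  window length L = n / (1 + 49·0.1); within each window the covariance
  matrix of the non-input indicators has its diagonal zeroed and the largest
  eigenvalue is recorded (it may legitimately be negative in noise); one
  curve per input indicator plus the panel mean.
* **L-Mode** — one-factor principal-axis extraction (SMC initial
  communalities, ≤ 100 iterations, tolerance 1e-6, Heywood communalities
  clamped at 0.995 with a warning), regression-method factor scores
  standardized to unit variance, Gaussian KDE with Silverman bandwidth on a
  512-point grid spanning the scores ± 4 bandwidths (so the density
  integrates to 1 within 1e-3 on the grid). Modes are strict local maxima at
  ≥ 1% of the peak density; with ≥ 2 modes the share of cases nearer the
  rightmost mode is reported as a base-rate estimate.

The cut/window counts, overlap, replication count and factor-score method
are conventional defaults, all exposed in configuration.

## Comparison populations

`reproduce_population` matches a target correlation matrix while preserving
marginals exactly: bootstrap each column from the source, generate
multivariate normal deviates under an intermediate correlation matrix
(initialized at the target), remap each normal column's ranks onto the
sorted bootstrap values, then add the residual (target − achieved) to the
intermediate matrix and repeat (≤ 10 iterations, keeping the iteration with
the smallest residual RMSR; tolerance 0.01 with a best-effort warning).
Intermediate matrices are kept positive definite by eigenvalue flooring at
1e-6 and rescaling to unit diagonal. Columns that are constant in a source
stratum carry no correlation signal and are excluded from the residual.

The categorical population ranks source cases on the unweighted total score
(seeded jitter breaks ties), labels the top round(p·n) as the putative
taxon, reproduces each stratum separately with its own marginals and
within-stratum correlations, and stacks them at round(p·N). The dimensional
population reproduces the full-sample correlation matrix once; since it does
not depend on p, the profile reuses one dimensional population (and its K
sample curves) across the whole base-rate grid. Samples are drawn without
replacement within a sample, independently across samples.

## Fit and aggregation

RMS distances pool residuals over all points of all K comparison curves
(`pool="mean-curve"` fits the band mean instead). L-Mode comparison curves
are evaluated on the empirical curve's density grid so curves share x
exactly; MAMBAC/MAXEIG grids agree by construction at equal n. The profile
summary is the unweighted mean over procedures × grid points (procedures
averaged per grid point only for the peak location); when both fits are zero
the CCFI is reported as 0.5 with a warning. The verdict bands are
< 0.45 dimensional, > 0.55 taxonic, ambiguous between — a symmetric band
reconciling the 0.50 decision point with the stricter 0.45 reporting
threshold used in applied work.

## Synthetic data

The generators exist so every downstream stage is testable without survey
data. Dimensional data are monotone discretizations of a single-factor
Gaussian model; taxonic data mix two equicorrelated Gaussian groups whose
means differ by a separation δ, with exactly round(p·n) taxon cases.
Marginals come from maximum-entropy pmfs on {0..6} matching a target mean
and SD (right-skewed whenever the mean is low, as symptom inventories are);
exact matching of skewness and kurtosis is not attempted — printed excess
kurtosis up to 13.4 is unreachable with 7-point support under a latent
normal. Because discretization attenuates correlations and separations, both
generators calibrate their latent parameters in a short Monte-Carlo loop
(4 iterations on an internal 20,000-case sample) so the *post-discretization*
mean r, Cohen's d and within-group r hit the requested values; recovery is
tested at n = 5,000. All randomness flows through one seeded generator, so
outputs are bit-reproducible.

Calibration presets encode indicator moments reported for large adolescent
gaming-symptom surveys: 9 DSM-5 indicators (means 0.31–0.92, SDs 0.84–1.52,
target mean r = .59) and the 4-indicator ICD-11 subset (target r = .61).
Without explicit marginal targets the generators default to a mildly
right-skewed marginal (mean 1.5, SD 1.5 on the 0–6 scale) and, for taxonic
data, equally spaced bin edges over the pooled mean ± 2.5 SD, which
preserves the mixture's shape.

What the synthetic data do **not** emulate: school-cluster sampling,
demographic covariates, missing-response mechanisms (inputs must be
complete), and item-level response processes (items are generated by
splitting indicators when needed). Passing tests therefore demonstrate that
the machinery recovers known latent structure under the stated conditions,
not that any particular real construct is dimensional.

## Problem sizes and simulation results

Desk-scale settings — comparison populations of 10,000, K = 10 samples, and
(for profiles) a base-rate grid of .05–.95 in steps of .05 — are used
throughout the test suite and the reproduction script; full-scale defaults
(100,000 / 100 / .025) match applied practice. Under desk-scale settings the
package's own experiments (see `scripts/acceptance.py` and
`tests/test_acceptance.py`) compute: the accuracy of the mean-CCFI rule over
50 datasets of known structure at n = 600; the mean CCFI profile of one
calibrated 9-indicator dimensional dataset at n = 2,000; the mean CCFI of
one planted-taxon dataset (p = .25, d = 2) at n = 1,000; and the location of
the profile peak over 10 planted-taxon replicates (true p = .2).

## Known limitations

* Extremely sparse indicators (means ≲ 0.6 on the 0–6 scale, i.e. mostly
  zeros) at modest n blur the distinction between the categorical and
  dimensional comparison populations; with the full survey-calibrated skew
  at n = 600 the decision rule loses accuracy on dimensional data. This is a
  property of the method, documented rather than patched; larger n restores
  separation.
* The categorical comparison model assigns the putative taxon by total-score
  ranking; constructs where class membership is not monotone in symptom
  burden are outside the model.
* MAXEIG requires ≥ 3 indicators; with 2-indicator sets the mean CCFI is
  taken over MAMBAC and L-Mode with a warning.
* CCFI values carry no confidence intervals; interpretation rests on the
  simulation-validated decision rule, not on sampling theory.
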