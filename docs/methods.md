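# Methods

## Model and scope

The package models pIC50 of 1,2,4-triazin-3(2H)-one derivatives as a linear
function of five molecular descriptors (χ, TE, NHD, LogS, I) by ordinary
least squares on 27 training compounds, with 5 held-out test compounds and
28 designed candidates carrying descriptors only. Descriptors are taken as
given inputs: computing them from structures (DFT orbital energies, topology)
is out of scope, except for the closed-form conversions between frontier
orbital energies and the derived electronic descriptors
(η = (E_LUMO − E_HOMO)/2, χ, ω) in `data_model.derived_electronic`, which are
exposed in both the study's printed sign convention and the textbook
(Mulliken/Parr) one.

Assumptions are the usual ones for a small-n MLR QSAR: linear response in the
chosen descriptors, i.i.d. Gaussian residuals, descriptors measured without
error, and validity restricted to the descriptor region covered by the
training panel (enforced by the leverage-based applicability domain).

## Data provenance and print irregularities

The compound tables ship as two CSVs transcribed from the original study's
printed tables. The source print concatenates digit runs, so the
transcription fixed column widths (2-decimal χ/TE/LogS, 1-digit NHD and I)
and was then audited against the study's own prediction column: regressing
the published per-compound predictions on the transcribed descriptors
reproduces them to <0.01 everywhere, which pins every ambiguous digit. Five
training rows (4h, 5i, 6a, 6f, 6i) print a shape-indicator digit that
contradicts the published prediction by exactly the I coefficient (0.36);
they are stored with the prediction-consistent value (I = 0) and flagged in
`data_model.DATA_NOTES`. Candidate Pred28's digit run admits a second
grouping under which the equation would give 6.01 instead of the printed
6.38; the uniform-pattern reading (I = 0, consistent, prediction 6.37) is
stored and the alternative recorded as a flag that the screening report
surfaces. Fixture files are checksummed at load.

## Coefficient provenance

The study prints the equation

    pIC50 = −10.12 + 1.64·χ − 5.69e−5·TE + 1.48·NHD − 1.37·LogS − 0.36·I

but OLS on the study's own training table gives
(−9.99, 1.61, −5.60e−5, 1.48, −1.36, −0.36), and — decisively — regressing
the study's *published predictions* on the descriptors recovers the same
coefficients with residuals <0.01: the model that generated the published
prediction column had the refit coefficients, not the printed ones. The two
vectors lie along a collinearity ridge (χ, TE and the intercept trade off
almost exactly over the observed descriptor range), so both predict
identically in-range; the printed equation is best read as a mis-rounded
report of the fitted model. The package therefore treats the refit as the
model and keeps the printed equation available as
`data_model.PUBLISHED_MODEL` for side-by-side comparison. One acceptance
test asserts the printed coefficients at printed precision and fails for
intercept/χ/TE, documenting the inconsistency rather than hiding it.

## Statistic conventions (desk-checked against the published tables)

Several formulas in the source are printed with defective denominators or
exponents. For each, the package defaults to the form that reproduces the
study's own reported numbers and keeps the literal printed form behind an
option:

- **R²**: standard denominator Σ(Yobs − Ȳobs)² reproduces 0.722; the printed
  denominator (about the predictions) gives ≈0.615 (`form="printed"`).
- **MSE**: RSS/(N − p − 1) reproduces 0.056; the printed /N form gives ≈0.044
  (`denominator="n"`).
- **External R²**: the squared Pearson correlation reproduces 0.710; the
  literal printed ratio is strongly *negative* on the study's test pairs
  (`mode="printed"`). The observed/predicted correlation on the 5-compound
  test set is in fact negative (r ≈ −0.84); squaring hides the sign, so the
  report also carries `test_correlation_sign`.
- **Rm² metrics**: rm2 = r²(1 − √|r² − R0²|) with an absolute-value radicand
  so the metric stays real when R0² > r². With the study's own through-origin
  convention the deltas match the published values to the digit
  (ΔRm² = 0.0005, ΔR0² = 0.001), but the Rm² mean computes to 0.333, not the
  published 0.530. The published 0.530 equals the cRp² radicand
  0.722 − 0.438² = 0.5302 exactly, so it is almost certainly a copy slip; the
  recomputed mean honestly fails the >0.5 checklist rule, and the package
  reports that failure (a direct consequence of the negative test-set
  correlation).
- **cRp²**: R·√(R² − (mean R_rand)²). The published 0.619 is reproduced when
  R is carried unrounded (√0.722·√0.5302 ≈ 0.6187); the rounded printed
  inputs give 0.618.
- **Q² (LOO)**: computed through the exact PRESS identity
  e(i) = e_i/(1 − h_ii); the explicit 27-refit loop is kept as
  `q2_loo_explicit` and used as the oracle in tests (agreement ~1e−9, limited
  by the conditioning of the raw-scale TE column).

Report tables round half away from zero to 3 decimals, matching the study's
formatting.

## Descriptor selection

The study describes "descendent selection and variable removal" without an
algorithm. Implemented as: iteratively drop the descriptor with the largest
p-value while it exceeds α = 0.05 (ties by descriptor order), then drop
descriptors with VIF > 10 (the study's stated ceiling), worst first,
refitting after every removal; the intercept is never removable and every
removal is logged. VIF is computed on the training subset by default
(configurable to all rows; the study's Table-3 basis is not recoverable, and
both bases agree with the published values to ~0.5).

## Applicability domain

Leverage h_i = x_iᵀ(XᵀX)⁻¹x_i with intercept-augmented rows. The study's
matrix dimensions are printed inconsistently; intercept augmentation is the
reading under which h* = 3(k+1)/n counts the k+1 fitted parameters. The
default reference set for the hat basis, for h*, and for the SDR
normalization is the full 32-compound panel (train + test), mirroring the
study's h* = 3·6/32 = 0.5625 ("printed 0.56") and its SDR equation with n =
"number of dataset molecules"; a train-only reference is available. SDR uses
the n-denominator RMS of the reference residuals (so the reference SDR series
has RMS exactly 1); a studentized variant is out of scope. The SDR band
defaults to ±3 with ±2.5 available (both thresholds appear in the source).
On the study panel no compound exceeds h* = 0.5625 or |SDR| = 2.5.

Most *designed* candidates, by contrast, carry leverage above h* — up to
h ≈ 17 for the candidate with TE ≈ −105 800, four times the panel's most
negative total energy. Their predicted activities (up to pIC50 ≈ 9.9) are
extrapolations and are flagged as such in the screening output.

## Y-randomization

Training responses are permuted without replacement (descriptors and split
untouched), the model refit, and R, R², LOO Q² recorded per iteration;
100 iterations by default, fully reproducible from a named seed, with
rank-deficient iterations recorded in `skipped` rather than silently dropped.
On the study panel the null averages (≈0.44 / 0.21 / −0.33) sit far below the
real model's statistics, and the null mean R² matches the theoretical
p/(N − 1) for regression on noise.

## Synthetic generator

`simulate.generate` draws descriptors independently — χ, TE, LogS uniform
over the study panel's stated ranges (χ∈[2.9, 4.1], TE∈[−106000, −22000],
LogS∈[−5.2, −2.7]), NHD categorical on {1..6}, I on {0,1} — and builds
y = β·x + N(0, σ) with the published-equation β and σ = 0.24 (the residual
RMS of the study fit). Optional nuisance descriptors are standard-normal
columns mixed (Cholesky-style) with a standardized informative column at a
requested correlation. The train/test split is a seeded permutation.

What the generator does *not* emulate: the real panel's inter-descriptor
correlations and its much narrower occupied ranges. Because the default
ranges span the designed compounds too, the default signal-to-noise is
higher than the study panel's (fitted R² ≈ 0.99 versus 0.72). Passing
recovery/selection tests on synthetic data therefore demonstrates estimator
correctness, not that real panels of this size always yield stable models.

## Numerical choices

- Least squares via statsmodels OLS (QR-based) and `numpy.linalg.lstsq` in
  hot loops; rank checked at relative tolerance 1e−10 with offending columns
  identified by pivoted QR before fitting.
- VIF ratios below 1e−12 are reported as infinite VIF rather than raising.
- Leverage uses an explicit (XᵀX)⁻¹ quadratic form (p = 5; conditioning is
  benign after the rank check) and is tested against a row-wise oracle.
- Degenerate inputs raise typed errors: non-positive IC50, zero HOMO–LUMO
  gap with ω requested, constant observed series, all-zero residuals,
  rank-deficient designs, empty models after elimination.

## Known limitations

- n = 27 training compounds with p = 5 descriptors leaves 21 residual
  degrees of freedom; coefficient standard errors are large and the χ/TE/
  intercept ridge (see "Coefficient provenance") means individual
  coefficients are only weakly identified even though predictions are stable.
- The 5-compound external set is too small for the external statistics to be
  meaningful on their own — its negative observed/predicted correlation
  despite R²_test ≈ 0.71 is the clearest symptom.
- The applicability domain is leverage-plus-residual only; distance-based or
  density-based alternatives are out of scope.
- Regularized, robust, or exhaustive-subset regression is out of scope.
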