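# Methods

## Signal model and scatter correction

The package treats an absorbance spectrum of a non-homogeneous sample as

    X_i = p_i * Σ_j c_ij * s_j + b_i * 1 + ε,

with multiplicative path factor `p_i`, additive baseline `b_i`, component
spectra `s_j`, concentrations `c_ij`, and i.i.d. Gaussian measurement
noise ε. The correction chain removes the sample-dependent nuisances in a
fixed order — additive first, then multiplicative:

* **LRC.** Each spectrum is regressed (simple least squares) on a
  reference mean spectrum; only the intercept is subtracted. The slope is
  deliberately retained: if the slope were divided out (as in MSC) the
  multiplicative structure needed by the subsequent ratio step would be
  destroyed along with it. The reference mean is always the *calibration*
  mean; prediction-set spectra are corrected against the stored
  calibration reference so no prediction-set statistics leak into the
  model.
* **S/S ratio.** After LRC, dividing a spectrum by its own value at a
  wavelength λ where `c_λ·s_λ` is sample-independent cancels `p_i`
  exactly. λ\* is chosen by brute-force search over the (trimmed)
  wavelength grid: for each candidate, the corrected calibration matrix
  is scored by the RMSECV of a PLSR model under Monte-Carlo
  cross-validation, and the argmin wins. Candidates where any calibration
  sample's LRC value has magnitude below 1e-6 are excluded as
  division-unstable. The all-ones column at λ\* is kept in the matrix
  (mean-centering inside PLSR annihilates it), so wavelength indexing
  stays stable across stages.

MCCV default: 70/30 random splits, 50 repetitions, seeded. The
experiment suite uses 20 repetitions for the λ search, which changes the
selected λ\* by at most a few grid points on the benchmark conditions.

## Wavelength selectors

All three selectors score candidate subsets identically: seeded shuffled
5-fold RMSECV of PLSR, latent variables by inner minimum up to 15 and
capped at the subset rank; one fold partition is drawn per selector run
and shared by every subset, so reported RMSECV values are directly
comparable and the winning subset re-scores to its reported value
exactly. Ties break toward smaller subsets, then lower starting index.

* **CARS**: 100 Monte-Carlo iterations. Each fits PLSR on a random 80%
  row subsample, weights variables by |regression coefficient|, keeps the
  top fraction given by the exponential schedule r(i) = a·e^(−k·i)
  calibrated so r(1) = 1 and r(N) = 2/p, then resamples the kept set
  proportionally to weight (adaptive reweighted sampling).
* **BOSS**: weighted bootstrap sampling of variables (p draws with
  replacement) generates sub-models; after scoring, each variable's
  weight becomes the sum of its normalized |PLSR coefficients| over the
  best 10% of sub-models. Weights — not hard eliminations — shrink the
  space; a variable leaves only when the winners stop using it. If a
  round fails to shrink the surviving set, the single lowest-weight
  variable is dropped, guaranteeing strict decrease and termination.
* **iVISSA**: a global phase updates per-variable inclusion
  probabilities (binary sub-models, best-10% frequency) until they
  saturate to {0, 1}; a local phase grows contiguous intervals around the
  surviving variables, one wavelength per side, while RMSECV improves by
  more than 1e-8. The result is a union of intervals, so this selector
  systematically keeps more wavelengths than CARS/BOSS.

Desk-scale run counts: the test and reproduction suites use 100
sub-models per BOSS round and per iVISSA round (library defaults: 1000
and 500) and cap iVISSA at 10 global rounds; on the planted-support
benchmarks the selections are unchanged beyond noise-variable churn.

## Regressors

* **PLSR** is SIMPLS with mean-centering only — scatter-corrected
  absorbance shares units across wavelengths, so autoscaling would
  amplify noise bands. One pass yields the regression vector for every
  latent-variable count, making the RMSECV loops inside the selectors
  affordable. Extraction stops when the score norm collapses (rank
  exhausted); zero-variance columns get exactly zero coefficient.
  Latent-variable count: minimum MCCV RMSECV (70/30 × 50 by default).
* **LS-SVR** solves the least-squares SVM dual system with RBF kernel
  `exp(−‖x−z‖²/σ²)` (the σ² convention, not 1/(2σ²)). Hyperparameters
  (γ, σ²) are tuned in log10 space over γ ∈ [1e−2, 1e8], σ² ∈ [1e−2, 1e7]
  — a box wide enough for the magnitudes seen on real fruit spectra — by
  seeded multi-start annealing (4 chains × 30 steps, 10-fold CV score)
  followed by a ±0.5-decade local grid. The solve is rejected if the dual
  residual exceeds 1e−6 relative.
* **ELM / PSO-ELM.** Inputs are min-max scaled to [−1, 1] (train
  statistics) so the sigmoid hidden layer operates in its responsive
  range; hidden weights/biases are uniform(−1, 1); output weights by
  least squares. PSO encodes the hidden layer as a particle (swarm 30,
  100 iterations, inertia 0.9→0.4, c1 = c2 = 2, positions clamped to
  [−1, 1]); fitness is seeded k-fold CV RMSE with output weights
  re-solved per fold. One particle starts at the seed-matched plain ELM,
  so the optimized CV fitness can never exceed the unoptimized one.
  Hidden nodes default to 30 for spectra and 15 for fusion stackers.

## Fusion

Members are PLSR models on wavelength subsets: MCMF uses the CARS, BOSS
and iVISSA selections (labels f1/f2/f3 in that order); CNCMF uses the
CARS subset (f4) and its complement (f5), a disjoint exhaustive partition
of the grid. Combiners: simple average; Bates–Granger weights
`w_k ∝ 1/v_k` with member variances taken from seeded 5-fold
cross-validated calibration residuals; OLS (MLR) stacking with intercept;
and LS-SVR / PSO-ELM stacking on the m-dimensional member-prediction
vector. Combiners are fitted on in-sample calibration member predictions
by default (matching how such stacks are usually reported); an
out-of-fold option exists for leakage-averse use. All members share one
MCCV stream for latent-variable selection, so identical subsets produce
identical members.

## Evaluation

Rc/Rp are Pearson correlations (not R²); RMSEC/RMSEP are root mean square
errors; RPD = SD(prediction-set reference values, n−1 denominator) /
RMSEP, with boundaries 1.4 and 2.0 assigned to the middle ("ordinary")
class and RPD reported as +inf when RMSEP is exactly zero. The 3:1
calibration/prediction split rounds the held-out count to the nearest
integer of n/4 by default (105 → 79/26); a round-up option gives the
alternative 78/27 partition. The published summary rows bundled in
`specfuse.published` satisfy the RPD identity to the printed 3 decimals.

## Synthetic data: what it does and does not emulate

`simulate.MixtureModelParams` defaults are the benchmark conditions used
throughout: 105 samples on a 600–900 nm grid (1 nm step), 3 components,
p ~ U(0.7, 1.3), b ~ N(0, 0.05²), noise SD 1e−3 absorbance, and the
target concentration mapped onto 9–17 to echo real SSC ranges (cosmetic
scaling). One component has constant concentration and a reserved
low-wavelength peak where it contributes >90% of absorbance, making the
S/S assumption literally true in a known region — the generator returns
that region so tests can check the search lands in it. The planted-
support generators (five singleton variables among 200, or two 8-wide
blocks sharing latent factors) serve the selector-recovery tests.

What the generator does not emulate: wavelength-correlated (pink) noise,
instrument drift, reference-method error on y (the reference values are
exact concentrations), nonlinear detector response, and the
water-dominated absorption background of real fruit. Two consequences
matter when reading test results. First, passing recovery tests show the
algorithms work where their assumptions hold, not that they attain any
particular accuracy on real spectra. Second, with exact reference values
and noise SD 1e−3 the regression task is nearly noiseless: full-spectrum
and member models reach RPD ≫ 3, far above the ~2–3 typical of real
fruit. At that ceiling the fusion combiners reproduce their exact
algebraic guarantees (the MLR stack never worsens calibration RMSE), but
the *qualitative* field observation that a nonlinear stacker lifts
prediction RPD above the best member has no room to appear — members
differ only at noise level, and the stacker tracks them within a couple
of percent rather than beating them. The corresponding check in the
acceptance suite documents this honestly rather than relaxing the
conditions.

## Numerical choices

* SIMPLS component loop stops at relative score norm 1e−12; excluded S/S
  candidates at |divisor| < 1e−6; iVISSA improvement tolerance 1e−8.
* Seeds: every stochastic stage derives its own stream from the global
  seed via a stable 32-bit blake2s hash (`crossval.derive_seed`), so
  stages are independently reproducible and permutation of stage order
  cannot silently couple them.
* Wavelength windows are closed intervals in nm. Absorbance elements with
  non-positive dark-corrected signal become NaN; a scan is rejected when
  more than 1% of its elements are invalid.
* Spectral tables are CSV with a wavelength header row and reserved
  `sample_id`/`y` columns, written at 17 significant digits and read with
  round-trip float parsing, so write→read is bit-exact.

## Known limitations

* The LS-SVR tuner is a generic annealing + grid scheme, not the exact
  coupled-simulated-annealing variant of the original LS-SVM toolbox;
  only the two-stage structure and the search space match.
* BOSS/iVISSA at their full run counts (1000/500 sub-models) are
  CPU-hungry; the desk-scale defaults used in the test suite trade
  sub-model count for runtime and are documented above.
* Fusion across acquisition geometries (combining DR/DT/FT spectra of the
  same fruit) is out of scope; fusion operates within one spectral mode.
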