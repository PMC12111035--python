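# Methods

## Problem setting

`flourspec` calibrates quantitative models that predict flour quality
indices — sedimentation value (SV, mL; gluten quantity/functionality) and
falling number (FN, s; inversely related to α-amylase activity) — from
near-infrared absorbance spectra in the 900–1700 nm window. The package
implements the full workflow: data splitting and standardization, ε-SVR
calibration with metaheuristic hyperparameter search, most-informative-
wavelength (MIW) selection, and external validation by two-sample tests.
Because no public flour spectra accompany this problem class at the grid
convention used here, a synthetic generator with planted ground truth makes
every algorithm testable end to end.

## Calibration model

The regression core is epsilon-insensitive support vector regression:
minimize ½‖w‖² + C·Σ(ξᵢ + ξᵢ*) subject to the ε-tube constraints, with an
RBF kernel by default. Three hyperparameters matter:

| parameter | meaning | search range | scale |
|---|---|---|---|
| C | regularization weight | 1e-2 … 1e3 | log-uniform |
| ε | insensitive-tube half-width | 1e-3 … 1 | linear |
| γ | RBF kernel width | 1e-4 … 1 | log-uniform |

The ranges comfortably bracket the optima typical of NIR calibration
(large C with very small γ on wide spectra; moderate C and γ after
wavelength selection). Fitting delegates to scikit-learn's libsvm-backed
SVR; a cross-implementation test checks predictions against R's e1071
wrapper to 1e-6.

All modeling happens in standardized space: spectra columns and the target
are centered and scaled by training-set statistics (population SD, i.e.
divide by n). Summary statistics in reports use the sample convention
(divide by n−1), which is what makes the pooled-variance arithmetic of the
validation block come out at its printed values. Reports carry both the
standardized errors and, when a target standardizer is attached,
back-transformed errors in mL or s.

Model quality is reported as the calibration-table row: R_CV and RMSE_CV
(arithmetic means of per-fold Pearson correlation and RMSE over a seeded
5-fold partition of the training set — shuffled contiguous blocks from a
seeded permutation), R_P and RMSE_P on the held-out prediction set, and
RPD = SD(prediction-set reference, n−1)/RMSE_P. RPD > 3 is the
conventional "suitable for quality control" bar. R is the Pearson
product-moment correlation of (reference, predicted), not the square root
of a fit-line R².

The train/prediction split takes round(0.8·n) training samples with
half-away-from-zero rounding; that convention reproduces 737/184 from
n = 921 and 723/181 from n = 904, whereas ceiling-on-the-test-side
conventions would not.

## Starfish hyperparameter search (SOA)

The hyperparameter objective — mean 5-fold cross-validated RMSE as a
function of (C, ε, γ) mapped from the unit box — is minimized by a
population metaheuristic organised around exploration and exploitation
phases with greedy replacement:

- **Initialization**: uniform in the box, seeded.
- **Exploration** (probability 1 − t/T at iteration t): each candidate
  moves toward the current best plus a random-weighted difference of two
  population members. The difference vector adapts proposal directions to
  the local geometry, which is what lets the search follow curved valleys
  (the Rosenbrock benchmark) rather than only descending isotropically.
- **Exploitation**: Gaussian refinement around a random elite (top 20%)
  with step σ(t) = 0.3·(1 − t/T)³ of the box width, shrinking to zero.
- **Regeneration**: the worst candidate is resampled uniformly each
  iteration (escape mechanism).
- **Greedy acceptance**: a proposal replaces its predecessor only if it
  improves the fitness, so the best-so-far trace is non-increasing by
  construction. Out-of-box proposals are clamped; NaN fitness rejects the
  candidate; a fully-NaN iteration aborts.

Budget: exactly pop·(iters+1) objective calls (defaults 30×51). The
stopping rule is the fixed iteration budget — no stagnation rule — to keep
evaluation counts comparable across runs. Benchmarks (frozen seeds): the
3-D sphere reaches < 1e-3 within the default budget, 2-D Rosenbrock
reaches < 0.1 in at least 18 of 20 seeded runs, and wrapping the CV
objective the search lands within 10% of a 20×20×20 log-grid optimum.

## Wavelength selection

Four selectors, individually and in two two-stage joint strategies, return
exactly k MIWs, reported with the reduction percentage
100·(p−k)/p rounded half-up to two decimals (20/360 → 94.44%,
30/360 → 91.67%).

**PCA (filter).** Components are retained to 95% cumulative explained
variance; wavelength j scores Σ_c evr_c·|V_cj| and the top k win, ties
toward the lower wavelength. The criterion is one defensible reading of
"PCA-based selection"; loadings are sign-indeterminate so magnitudes are
used.

**SPA (successive projections).** Classic forward selection: starting from
a chosen column, repeatedly project all remaining columns onto the
orthogonal complement of the selected set and add the column of maximal
projected norm. With `start_index="auto"` every start column is tried and
the chain minimizing a least-squares CV RMSE against y is kept.
SPA must see *centered but unscaled* spectra: autoscaling equalizes column
norms and removes exactly the magnitude information the projection
criterion ranks by (on autoscaled data SPA degenerates to picking the most
mutually orthogonal columns, which favors pure noise). The joint-strategy
API therefore accepts a separate `X_spa` matrix.

**RFE (wrapper, backward).** scikit-learn RFE over a linear-kernel SVR,
ranking columns by squared weight and dropping the lowest per round. In
joint strategies the screening stage drops ~5% of surviving columns per
round for tractability on 360-point grids; standalone calls default to
one-at-a-time elimination.

**iWOA (wrapper, swarm).** A binary improved whale optimization algorithm:

- *Chaotic initialization*: whale positions come from logistic-map orbits
  x_{t+1} = 4x_t(1−x_t); seeds avoid the degenerate orbit points
  {0, 0.25, 0.5, 0.75, 1} (x₀ = 0.5 maps to 1 and then sticks at 0).
- *Sigmoid-scheduled coefficient decay*: the encircling coefficient a
  decays 2 → 0 along a sigmoid in t/T instead of linearly, keeping the
  early phase exploratory and the late phase strongly exploitative.
- *Position updates*: the three whale behaviors — encircling the best,
  log-spiral attack, random-whale search — on continuous positions in
  [0,1]^p, clamped.
- *Transfer*: positions pass through a sigmoid and the k columns clearing
  the implied rank threshold (perturbed by a small seeded jitter draw)
  form the inclusion mask. Design note: the textbook per-column Bernoulli
  transfer was implemented first and measured; with p ≫ k it concentrates
  masks near p/2 columns and cannot reach the cardinality target within a
  ~10³-evaluation budget, and per-evaluation redraws make greedy
  acceptance chase draw noise. The rank-threshold transfer holds every
  mask at exactly k, makes the mask a near-deterministic function of
  position (so moving toward the best whale inherits its columns), and
  keeps a seeded stochastic element for exploration.
- *Fitness*: CV RMSE of a regression on the masked columns plus a
  per-column cardinality penalty (0.05·SD(y) per deviating column — a
  safeguard; the rank transfer already enforces k). The faithful objective
  is SVR CV; the default inner estimator is a closed-form ridge CV
  (α = 1), which ranks masks the same way at a small fraction of the cost
  — selectable via `BinarySwarmConfig.fitness`.
- *Greedy replacement* throughout; the best-fitness trace is
  non-increasing and runs are bit-reproducible from the seed.

**Joint strategies.** `iwoa_spa` screens p → pool with iWOA then refines
to exactly k with SPA; `rfe_iwoa` screens with RFE then refines with iWOA.
The literature this follows never states the stage order; coarse global
screening before exact-cardinality refinement is adopted, and a
`reverse_order` switch exists for the converse. Pool sizes are nowhere
specified either; the default is 3k. Reduction is always reported against
the original p.

**Screeners.** `screen_features` offers a binned mutual-information filter
(equal-frequency bins, plug-in estimator, bin count ≈ √n capped at 8) and
a kernel-PCA proxy (eigenvalue-weighted |correlation| of each column with
the kernel component scores).

Permutation consistency: the deterministic selectors (PCA, SPA, RFE)
commute exactly with column permutations; the stochastic wrapper (iWOA)
is permutation-consistent in distribution only, since its seeded draws are
indexed by column position.

## Two-sample validation report

The external check compares n = 50 measured values against the model's 50
predictions.

- **F-test** for variance homogeneity: F = s²_measured / s²_predicted
  (measured in the numerator — the reporting convention reproduced here,
  not larger-over-smaller), one-tailed p from the upper tail when F ≥ 1
  and the lower tail otherwise, critical value F⁻¹(1−α; n₁−1, n₂−1).
- **Pooled t-test** for mean bias: s²_p = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),
  t = (x̄₁−x̄₂)/√(s²_p(1/n₁+1/n₂)), df = n₁+n₂−2, one- and two-tailed
  p-values and critical values at α. The pooled (equal-variance) form, not
  Welch, is what a "merged variance" row implies.

At α = 0.05 with two groups of 50: F critical 1.6073, t critical 1.9845
(two-tailed) / 1.6606 (one-tailed); pooled variance of group variances
42.1 and 39.0 is 40.55 → 40.6 at one decimal. Reports render with display
rounding (1 dp summaries, 4 dp statistics) and serialize at full precision;
a report can regenerate all statistics from its stored summaries within
1e-9 (self-consistency invariant).

A subtlety exercised by the tests: a "prediction-like" pair built as
predicted = measured + noise is *not* a null for the F-test — additive
independent noise inflates the predicted-group variance. The type-I-error
simulation therefore draws two independent equal-variance groups
(`make_validation_pair(..., null_mode="independent")`), under which the
one-tailed rejection rate matches α within the binomial CI at 1000
repetitions.

## Synthetic spectra generator

Flour spectra in this window are dominated by broad X-H overtone bands:
~930 nm (third O-H overtone + C-H combinations), ~1200 nm (second C-H
overtone), ~1460 nm (first O-H overtone of water). The generator emulates:

    A(λ) = Σ_j c_j · a_j · exp(−(λ−μ_j)²/2w_j²)  +  drift(λ)  +  N(0, σ_noise)

with per-sample concentrations c_j ~ U(0.5, 1.5), a nonnegative random
quadratic baseline (amplitude 0.05), and spectral noise σ = 0.002
absorbance units. The target is a linear recipe on the concentrations
(optionally plus a quadratic term), standardized, noised on the z-scale
(σ = 0.1, implying a correlation ceiling ≈ 0.995), and rescaled to a
realistic mean/SD. Defaults:

- grid: 360 points spanning 900–1700 nm (the nominal device convention;
  note 2.6 nm steps over that span would give ~308 points, so the grid is
  treated as data and only monotonicity is validated);
- bands: Gaussians at 930/1200/1460 nm with σ = 45/40/55 nm (broad
  overtone widths), weights (1.0, −0.7, 0.5);
- presets `sv_like` (mean 29.0, SD 6.4 mL) and `fn_like` (mean 334, SD
  38 s) to exercise both unit paths.

Ground truth: a wavelength is "planted informative" if it lies within 3
grid steps of a nonzero-weight band center; the truth object also carries
the concentrations and recipe weights.

**Localization preset.** For planted-band *recovery* experiments the
`localized` preset uses six σ = 5 nm bands (930, 1060, 1200, 1330, 1460,
1600 nm), all with nonzero weights, and no drift. Two reasons, both
structural: (i) with broad bands the informative signal spans tens of grid
steps, so demanding picks within ±3 steps of a center would be ill-posed;
(ii) wrapper selectors and SPA keep at most ~one wavelength per latent
band — once a mask covers every band, additional in-band columns are
statistically redundant and the fitness cannot prefer them over noise — so
a k-pick recovery experiment needs at least k distinct planted bands. The
recovery suites accordingly use k = 6 with the default 3k pool.

What the generator does **not** emulate: scatter effects and their
preprocessing (SNV/MSC/derivatives), instrument drift between sessions,
cultivar-by-environment structure, wavelength-dependent noise, or any
radiative-transfer physics. Passing the recovery and parity suites shows
the algorithms behave as specified on data with known low-rank band
structure; it does not certify performance on real flour spectra.

## Numerical choices and degenerate inputs

- Split rounding: half away from zero on the training fraction.
- Standardization: zero-variance columns are flagged and given scale 1
  (transformed values exactly 0); transform∘inverse is identity to 1e-10.
- SPA declares exhaustion when all projected norms fall below 1e-12
  (rank-deficient input) and reports the attained size.
- Pearson correlation raises on constant input rather than returning 0.
- RPD raises on zero RMSE; the report invariant RPD·RMSE_P = SD(reference)
  holds to 1e-9.
- PCA ties break toward the lower wavelength index.
- The SOA trace includes the post-initialization best, so its length is
  iterations + 1.

## Problem sizes in tests and the acceptance script

The test and acceptance workloads are deliberately desk-scale, chosen so
the full suites exercise every claim on one CPU: synthetic calibration
uses n = 200 samples × 360 wavelengths with SOA budgets of 15×20; the
grid-parity check uses n = 60 × 20 wavelengths against a 20³ grid;
recovery suites use 20 seeds at n = 120 (360 columns) and n = 60 (30
columns); the type-I simulation uses 1000 repetitions. Published-scale
inputs (n = 921/904 flour samples) appear only in the split-size and
reduction accounting, which are exact at any scale.

## Known limitations

- The SOA here is a contract-first implementation of the published
  qualitative description (exploration/exploitation/regeneration, greedy
  selection); it is not a line-by-line reproduction of any specific
  reference, and "gradient-informed adjustment" is realised as the
  elite-refinement phase, not a literal gradient.
- iWOA's planted-column recovery is seed-dependent (mean ≈ 0.8–0.9 over
  20-seed panels on the 30-column task); RFE is essentially exact there.
- The pca-selection criterion and the joint-strategy stage order/pool
  sizes are defensible choices among several; all are exposed in config.
- `screen_features`' kernel-PCA mode is a heuristic proxy (no exact
  pre-image exists for RBF kernel PCA).
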