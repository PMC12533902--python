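# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the places where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and shape

The package is a library-first artifact: the importable API plus the
narrative scripts in `examples/` are the primary interface, with a thin
`cilad` CLI for shell use.  All four data modalities (ECG beats, cardiac
images, tabular records, wearable metadata) flow through the same chain —
generate → preprocess → extract → select → split → train → evaluate — and
the nutrition recommender consumes the classifier's risk score as part of
the patient profile.

The neural components (CILAD-Net and the PPO policy/value network) run on a
compact reverse-mode autodiff core (`cilad.nn`) written on NumPy.  Keeping
the differentiation engine inside the package makes the whole artifact
dependency-light and every gradient inspectable; the core implements only
the ops the two networks need and is verified against numeric
differentiation in the test suite.  Tensors default to single precision
(the conventional deep-learning choice); `set_default_dtype` switches to
float64 where high-precision checks need it.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions; their defaults are fixed and
not tuned per experiment.

- **ECG beats** (`gen_ecg_beats`): sums of Gaussian bumps (P, Q, R, S, T)
  with class-dependent amplitudes, positions and QRS widths (80/64/120/96/48
  ms above a 0.2-of-peak threshold), white noise (default sd 0.05 on a
  unit-amplitude R wave) and sinusoidal baseline wander whose amplitude
  defaults to the noise sd so noise-free tables are exactly the templates.
  Beat length 187 at 125 Hz matches the common single-beat CSV dialect.
  A `separation` dial interpolates class templates toward the reference
  class; tests verify a capacity-limited linear classifier's accuracy rises
  monotonically with it.  This is a geometric beat model, not a
  physiological simulator: no rhythm context, no inter-beat dynamics, no
  electrode artifacts.  Passing tests show the pipeline machinery works on
  class-structured quasi-periodic signals, not that it would reach the same
  numbers on hospital recordings.
- **Cardiac phantoms** (`gen_cardiac_images`): elliptical-annulus
  "myocardium" with class-controlled wall thickness (0.18/0.34/0.10 of the
  outer radius) and cavity eccentricity (0.30/0.45/0.62), smoothed-noise
  texture, and exact annulus masks.  Geometric, not anatomical.
- **Patient records / metadata** (`gen_patient_records`, `gen_metadata`):
  latent standard-normal features mapped to UCI-style display scales; the
  binary target follows a logistic model over a seeded subset of features
  (coefficients in `meta["coefficients"]`, tags in `provenance`).  Defects
  are injected deliberately: missing cells, mean ± 6σ outliers (guaranteed
  to trip the z = 3 rule at small fractions), and exact duplicate rows
  (⌊frac·n⌋ of them) for the cleaning stage.
- **Food database / profiles** (`gen_food_db`, `gen_patient_profile`): 20
  per-serving archetypes with ±8% jitter; profile bounds encode one day of
  adult guidance — sodium ≤ 2300 mg, saturated fat ≤ 13 g, fiber ≥ 25 g,
  calories 1800–2200 kcal, cholesterol ≤ 300 mg — as *data on the profile*,
  not constants in code.  These are defaults inspired by published dietary
  guidance, not values any specific source prints.  Hypertension profiles
  up-weight sodium in the risk term; dyslipidemia up-weights cholesterol
  and saturated fat.

## Preprocessing choices

- **Wavelet denoising**: discrete decomposition (db4, level 3), noise scale
  from the finest detail band by the MAD rule, universal threshold
  σ√(2 ln n) applied to all detail bands.  The default shrinkage is
  **hard** thresholding: on 187-sample single beats the soft rule's
  constant shrinkage of every surviving coefficient visibly over-smooths
  the QRS complex (about 1.4 dB worse output SNR in the package's own
  measurement), while keep-or-kill preserves the large QRS coefficients.
  Soft shrinkage remains one flag away.
- **Degenerate min-max range** (max = min): mapped to the lower bound with
  a warning rather than an error — constant columns occur in small
  synthetic tables and should not abort a pipeline.
- **Z-score outliers**: threshold 3.0 by default; flagged values are
  winsorized to μ ± 3σ (configurable to report-only).  σ = 0 yields no
  flags.
- **Categorical encoding**: first-appearance integer codes, with the
  mapping persisted so transforms replay identically on held-out data.
  Normalization statistics are fit once and replayed (fit-on-train) —
  standard leakage avoidance.
- Duplicate detection is exact over all columns; no fuzzy record linkage.

## Feature extraction choices

- The periodogram uses the squared-magnitude form |DFT|²/T (one-sided,
  Parseval-consistent); a flag restores a plain-magnitude variant for
  comparison.
- QRS onset/offset: the contiguous region around the global
  absolute-amplitude peak exceeding θ = 0.2 of it; duration counts samples
  in the region, so a k-sample rectangular pulse measures k/fs seconds.
  This is the simplest defensible detector for single-beat rows.  For the
  wide-QRS beat classes the planted R-bump width is *not* the
  above-threshold width, because deliberately overlapping S deflections
  distort the complex — the tests use the isolated-QRS classes for the
  planted-truth check.
- True NN-interval sequences do not exist in per-beat tables, so the ECG
  schema carries a within-beat peak-interval spread as an SDNN proxy,
  documented as such; `hrv_sdnn` itself operates on genuine interval
  sequences.
- GLCM: distance 1, the four standard angles, 16 uniform quantization
  levels, symmetric and normalized; energy is the angular second moment
  Σ P², entropy uses natural log with 0·log 0 = 0, and a single-gray-level
  matrix has correlation defined as 1.
- LBP: radius 1, 8 neighbors on integer-rounded circle offsets starting
  east and counter-clockwise, s(0) = 1, border pixels excluded.  This exact
  raster convention is pinned by a per-pixel loop oracle in the tests.
- Moments are population quantities (divisor n); kurtosis is excess
  (normal → 0); a constant sequence defines skewness/kurtosis as 0.

## Selection choices

- ReliefF: L1 distance on internally min-max-scaled features; k = 10
  neighbors; all instances visited in deterministic order by default
  (seeded subsampling optional); δ = 1/m so weights are averages; misses
  weighted by class prior over 1 − P(own class).  The update uses the
  classical orientation (NMAD − NHD: near hits and far misses raise the
  weight).  A `literal_sign` flag provides the opposite printed variant,
  which rewards features whose hits are far — kept only for comparison.
- Fusion: α = 0.5 by default; both signals min-max rescaled to [0, 1]
  (|PC| taken first); ranking ties break by ascending feature index for
  determinism.  A brute-force ReliefF with explicit loops serves as the
  exact oracle for n ≤ 50.

## CILAD-Net choices

Filter counts 32/64/128 and LSTM width 64 are the architecture's defining
constants; everything else the design leaves open is config-exposed with
these defaults: kernel 3, pool 2, inception branches of 16 channels each
(1/3/5 convolutions plus a pooled 1×1 branch, 'same'-padded and
channel-concatenated), FC head 128→64, dropout 0.5, Adam at 1e-3, batch 32,
20 epochs.  The LSTM consumes the inception output with positions as time
steps and only its final hidden state feeds the head.  The second pathway
is read literally as conv(128) → ReLU → maxpool → batchnorm, flattened.
The model is instantiated per modality on its 1-D input (raw beats, or the
selected feature vector); no cross-modal fusion layer exists because
results are reported per dataset.  Inputs are z-standardized with
statistics fit on the training split.  Class-absence in training labels is
an error; shape validation reports the minimal admissible input length for
the pooling chain.

Desk-scale study conditions: the learning-sanity experiment uses 500
beats/class for training and 100/class for testing across 5 classes with
the default configuration — sized so the full suite and the acceptance
script run comfortably on a single CPU while still exercising every layer.

## Metrics choices

Per-class metrics default to macro averaging (micro and weighted are
available and the report records the mode).  R² on integer-coded labels is
statistically odd but part of the report's contract; it is computed
literally, with the constant-truth degenerate case defined as 1 for perfect
prediction and 0 otherwise.  Single-observed-class kappa/MCC are defined as
0 with a warning.  `accuracy + hamming_loss = 1` holds exactly for
single-label tasks and is asserted.

## Nutrition MDP choices

- The action mask enforces only the upper bounds, exclusions and forbidden
  tags per step.  Enforcing the guideline *lower* bounds per step would
  deadlock the first meal (no single item reaches a day's fiber minimum),
  so they are enforced terminally: a shortfall penalty
  −(1/d)Σ max(0, ℓ_i − c_T,i)² is folded into the adherence component at
  the terminal step, preserving the exact reward decomposition.
- Adherence and risk are computed on guideline-normalized units (intake
  divided by the per-nutrient target), making the penalties dimensionless
  and comparable across nutrients whose raw scales differ by three orders
  of magnitude.  The per-step adherence target is pro-rated, g_i·(t+1)/H,
  with the full daily target at the terminal step — dense shaping toward
  an end-of-day goal.
- "Preferences satisfied" means the item carries all required tags and no
  forbidden tag; forbidden tags are additionally masked, so the soft
  preference term mainly prices missing required tags.  RepCount counts
  exact item-id repeats within the episode only.
- Default weights α=1, β=1, γ=0.5, δ=0.3, η=0.1, λ_viol=1, ρ=0.5, k=0.05;
  portion sizes are not modeled (discrete items only).

## PPO choices

Shared two-layer tanh trunk (64 units) with separate policy and value
heads.  State encoding: normalized profile scalars, fractional intake
c/u, normalized step index, and a chosen-before indicator per item.
Masking adds −1e9 to infeasible logits before the softmax, so sampling
probability is zero and the entropy term covers feasible actions only.
Defaults ε=0.2, c_e=0.01, c_v=0.5, γ=0.99, λ=0.95, lr=3e-4, rollout 1024,
4 epochs, minibatch 64, advantage normalization per minibatch (flagged,
since it is a stabilization choice).  GAE is applied per episode with a
zero terminal bootstrap; whole episodes are collected until the rollout
quota is met.  The elementwise min of the clipped surrogate is implemented
by branch masking; the clipped branch is constant with respect to the
parameters, as in reference implementations.  The toy learning experiment
(20 items, horizon 5, 200 updates, 5 seeds) measures mask safety, the
fraction of nondecreasing adjacent 10-update windows of the smoothed mean
episode reward, and the final terminal-adherence penalty.

## Known limitations

- Synthetic generators are deliberately simple; results quantify the
  pipeline's internal correctness and learnability on planted structure,
  not clinical performance.
- The ReliefF oracle equivalence is exact only because both paths share
  the distance and tie-break conventions documented above; other ReliefF
  variants (diff normalization by feature range on unscaled data, distance
  weighting) would produce different weights.
- The CLI is a thin wrapper; long experiments (the acceptance conditions)
  live in `scripts/acceptance.py` and the test suite rather than behind
  CLI flags.
- Single-label classification only; no probability calibration or ROC
  analysis.
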