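# Methods

This note records the models, parameter choices, and numerical conventions
behind `sonofc`, and what the synthetic studies do and do not establish.

## Generative model

Node signals are a vector AR(1) process
x_t = Φ x_{t−1} + ε_t, with diagonal Φ (default coefficient 0.4 for every
node) and innovation covariance Q = Σ ∘ (1 − φφᵀ) chosen so the stationary
covariance equals the prescribed network covariance Σ exactly. The process is
initialised from N(0, Σ), so it is stationary from the first sample; a
Monte-Carlo check at T = 5000 reproduces Σ to ~0.04 max-abs. An AR(1) at
TR = 2 s is the simplest model with BOLD-like temporal autocorrelation; no
hemodynamic convolution is attempted. Heterogeneous per-node coefficients are
allowed but Q must remain positive semi-definite (checked; a clear error
otherwise).

Σ is block-structured with unit variances: correlation 0.6 within a
functional module and 0.15 between modules. The default 14-node atlas mirrors
an amygdala/ACC fingerprint constellation (amygdala, ACC, OFC, lateral OFC
47/12o, dlPFC, frontal pole, mid- and posterior cingulate, anterior temporal,
striatum, M1, pIPS, F5c, A1), with a limbic/prefrontal module and a
sensorimotor module. Cingulate structures are midline; every other node is a
left/right region pair sharing the node signal. Each hemisphere region has 5
points; a point observes its node's signal plus independent N(0, 1) noise.
The 0.6 / 0.15 couplings were fixed a priori as typical anesthetized-primate
inter-areal magnitudes. The atlas is fully user-overridable (JSON/YAML); no
spatial geometry is modelled, so "points" carry no coordinates and no
smoothing kernel exists.

**Decoupling.** The intervention replaces a fraction 1 − δ of the target
node's signal variance with independent noise: x'_k = √δ·x_k + √(1−δ)·η.
Cross-covariances of the target scale by √δ, its variance is unchanged, and
the covariance stays positive definite for every δ ∈ [0, 1]. δ = 1 is a
no-op; δ = 0 isolates the node.

**Artifacts.** The default injected battery per run: linear drift of
10⁻³ signal units/s common to all points; a 0.3 Hz respirator-like sinusoid
(amplitude 1, random phase) — note that at TR = 2 s the Nyquist frequency is
0.25 Hz, so this component appears at its 0.2 Hz alias, which is exactly what
a sampled recording would contain; one spike volume (amplitude 8); and a
unit-weight leak of a random linear combination of the recorded B0 traces
plus the WM and CSF compartment means, with per-point loadings ~N(1, 0.09).
B0 traces are smoothed random walks; compartment signals are three shared
smooth latents plus white noise, so their means and leading PCs carry the
structured part. Because the leaked signal lies in the span of the recorded
confounds, nuisance regression can remove it exactly; this is deliberate —
the generator tests the plumbing, not confound-model mismatch.

## Cleaning chain

Order is fixed: discard → despike → high-pass → band-stop → nuisance
regression → low-pass → demean → concatenate (→ group-PCA). All steps are
per-run until concatenation.

- **Despike**: robust z (median/MAD, Gaussian-scaled) of the first-differenced
  cross-point mean signal; an entering jump is paired with the next opposite-
  sign jump within 10 volumes and the volumes between are replaced by linear
  interpolation across clean neighbours (endpoints: nearest clean value).
  Threshold 5; on white noise the per-volume false-positive rate is ~6·10⁻⁷.
- **Filters**: Butterworth order 2, applied as the squared magnitude response
  in the frequency domain. This is exactly zero-phase and exactly symmetric
  under time reversal (machine precision), with the same squared-magnitude
  response a forward-backward IIR pass has but none of its edge transients.
  The high-pass removes the mean and linear trend outright (both lie below
  any admissible cutoff) before filtering. A 2000 s cutoff is not
  representable on a standard 1590 s run; the step then degrades, with a
  logged warning, to mean+linear+quadratic detrending. The 10 s low-pass
  attenuates a Nyquist-frequency probe by ~98% and passes 0.02 Hz at ~99.9%.
- **Dynamic band-stop**: Welch log-power (nperseg 256) averaged across
  points; peaks within the search band (default 0.1 Hz–Nyquist) exceeding
  median + 6·MAD (MAD on the Gaussian-σ scale) are notched (half-width
  0.01 Hz). The 6σ robust threshold never fires on white noise at realistic
  run lengths (measured: 0 of 100 trials) while an amplitude-5σ sinusoid is
  detected essentially always and attenuated far beyond 20 dB.
- **Nuisance design**: WM and CSF compartment means plus each compartment's
  first two principal components (computed on demeaned signals;
  rank-deficient compartments contribute the PCs they have, with a warning),
  and per B0 trace the second-degree Volterra set {x(t), x(t−1), x(t)²,
  x(t−1)²} on the raw traces (24 columns for 6 traces), plus an intercept.
  Cross terms x(t)·x(t−1) are available behind a flag but off by default, in
  line with common motion-expansion practice. Regression uses the
  pseudoinverse, so collinear or constant columns are harmless; residuals are
  orthogonal to every column to ~10⁻¹².
- **Group-PCA**: the reduced representation is S_n·V_nᵀ from the SVD of the
  temporally concatenated stack: its point-space covariance equals the
  stack's restricted to the top-n subspace, and it matches a direct
  eigendecomposition to < 10⁻⁶ rad in principal angles. Default
  dimensionality min(500, points). Connectivity can be computed either on
  per-subject concatenated series (the default and what the cohort drivers
  use) or on the group-PCA output; both entry points are exposed.

A per-run `truncate_last` config field supports dropping a noisy trailing
epoch of a specific run without special-casing the pipeline.

## Connectivity and inference conventions

- Correlations are Fisher z-transformed with |r| clipped at 0.999999, so
  self- and copied-point correlations stay finite (z ≈ 7.25); a flag excludes
  seed points from their own ROI average instead. Zero-variance points get
  r = 0 with a logged warning rather than NaN.
- A fingerprint entry is the map's mean over each hemisphere region's points,
  then the mean of the two hemisphere means; the seed is always excluded from
  its own fingerprint.
- The permutation test statistic is the cosine similarity of the two
  condition-mean fingerprints (runs averaged within condition). Labels are
  exchanged at the run level by default; a subject-level option keeps each
  subject's runs together, since run exchange across animals ignores
  within-subject dependence (in the generator runs are independent given the
  group network, so run exchange is exactly valid there). When the balanced
  label space has at most n_perm distinct splits the null is enumerated
  exhaustively and flagged as such. The p-value is the plain proportion of
  null similarities ≤ observed (one-tailed toward dissimilarity); the
  (b+1)/(n+1) convention and a two-sided tail are available by flags. A
  zero-norm fingerprint is an error; all-identical fingerprints degenerate to
  observed = 1, p = 1 with a warning.
- Impact maps use the sign convention control − TUS (coupling reductions are
  positive) over the a-priori region set, which must exclude the sonicated
  targets; per-region unsummed deltas are returned alongside the summed map.
- The mediation statistic is the Pearson correlation, across the fingerprint
  targets shared by both seeds, between the auditory seed's coupling change
  and the sonicated seed's coupling change, with a parametric two-sided p by
  default (permutation option). With ~12 targets and shared sampling noise
  this is a noisy descriptive quantity: under the generator's null (A1
  untouched) r ranges roughly ±0.8 across cohorts.
- The temporal-variability control is the per-region mean of per-point
  temporal SD, compared between groups with a two-sided permutation test per
  region. It is a simplified stand-in for a fuller amplitude analysis;
  per-run summaries are strongly correlated across regions, so the count of
  sub-α regions moves as a block.

## Study sizes and operating characteristics

The replication battery (`sonofc.study`, `scripts/acceptance.py`) uses the
experiment's group structure (9 control vs 4 TUS subjects, 3 runs each) with
200-volume runs and 1000 permutations, sizes chosen so the full battery runs
in minutes on a single core while keeping each test's Monte-Carlo error far
below the margins being asserted. Measured with these defaults:

- type-I error 0.02–0.09 at α = 0.05 under δ = 1;
- impact-map localisation to the decoupled node in ≥ 90% of cohorts at
  δ = 0.4, with a distant control seed rejecting at ≈ α;
- cleaning strictly improves the node-correlation estimate in ≥ 95% of
  artifact-laden runs.

One characteristic deserves emphasis: because decoupling scales *all* of the
target's cross-couplings by the same √δ and cosine similarity deliberately
ignores fingerprint amplitude, the intervention's asymptotic effect on the
test statistic is nearly nil (arctanh curvature contributes ~5·10⁻⁵ of
shape change). The test's power therefore comes from the reduced
signal-to-noise of the TUS group mean, rises steeply only at strong
decoupling (≈ 0.9 at δ = 0.1, 1.0 at δ = 0), and plateaus near 0.2–0.4 at
δ = 0.4 regardless of run length. Real interventions are unlikely to scale
every coupling uniformly, so this is a property of the synthetic effect
model, not of the inference machinery; a non-uniform decoupling would show
shape-driven power.

## What passing tests do and do not show

The generator emulates the study's group/run structure, artifact classes,
and a parametric coupling intervention, but not: hemodynamic convolution,
spatial autocorrelation or geometry (no smoothing, no registration),
subject-level random effects (runs are exchangeable by construction),
physiological noise with drifting frequency, or confounds outside the span
of the recorded traces. Passing the battery shows the pipeline recovers
known truth under these idealisations; it does not certify performance on
real data where those assumptions fail.
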