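# Methods

This document describes the models implemented in `veplink`, the semantics of
the synthetic-data generators, and the design decisions behind defaults.  It
is the reference for *what is computed*; the README covers *how to run it*.

## 1. Stimulus generation (`veplink.stimgen`)

A display is a square field (default 1000 px, 17° of visual angle) of
non-overlapping Gabor elements on mid-grey, containing a Gaborized ellipse
defined by two independent cues:

- **Contour cue** — 43 elements at equal arc-length spacing on the outline of
  an ellipse (major axis default 11.8°, axis ratio 1.2), each oriented along
  the local outline tangent.
- **Surface cue** — 150 iso-oriented elements (−45° from vertical) inside the
  outline.
- **Background** — 397 uniform-random-orientation elements outside.

Cue reliability is degraded by adding i.i.d. Gaussian orientation jitter
(SD in degrees) to the cue-carrying elements.  The ellipse centre is displaced
by 0.69° along one of the four meridians (seeded choice), so that absolute
position is uninformative.

**Orientation convention.** Degrees away from vertical, clockwise positive.
Contour tangents are computed analytically from the ellipse parameterization
and stored per element, so jitter draws are exactly recoverable from the
element table (`orientation_deg − tangent_deg`).

**Placement.** Surface and background elements are dart-thrown (uniform
candidates, rejected when closer than `min_center_spacing_px` = 26 px to any
placed element, or on the wrong side of the outline with a 3% exclusion band
around it).  Packing failure is detected by a bound on *consecutive* rejected
candidates and raised as `PackingError` naming the dense region.

**Density screen.** For every element, the mean Euclidean distance to its 4
nearest neighbours (over all elements; a `within_region` switch restricts the
search) is computed with a k-d tree.  Welch's unequal-variance t-test compares
the per-element distances for each region pair; the display is accepted iff
all three p-values exceed α = 0.1.  `generate_accepted_display` retries with
incremented seeds until a display passes.  The default ellipse size (11.8°)
was chosen so that interior and exterior densities balance under dart-throwing
and the screen rejects only unlucky draws (~50% acceptance); with the default
geometry the mean 4-NN distance is ≈ 40 px ≈ 40 arcmin.

**Rendering.** Each Gabor is an oriented sine grating (default 3 cycles per
0.7°, Michelson contrast 0.5, uniform-random seeded phase) times a circular
Gaussian envelope (SD 3.8 arcmin), added to the 0.5 background and clipped to
[0, 1].  The nominal Michelson contrast is a property of the grating; the
empirical `(max−min)/(max+min)` of a rendered patch equals it only when the
envelope is broad enough to expose a full luminance trough (the tests verify
this with a broad-envelope patch).  `make_noise_mask` returns uniform pixel
noise of display size.

## 2. Psychometrics (`veplink.psychometrics`)

**Four-parameter probit.**

    P(correct | j) = g + (1 − g − l) · Φ((μ − j) / s)

with guess rate `g` and lapse rate `l` free in [0, 0.5].  The **threshold** is
μ (the inflection point, midway between the asymptotes `g` and `1 − l`); the
**slope at inflection** is `−(1 − g − l)·φ(0)/s`.  Fitting is maximum
likelihood (binomial) with bounded L-BFGS-B and 10 seeded multistarts.
Performance flat at ceiling or at chance across all levels is declared
non-identifiable: `converged=False` with a diagnostic, never a fabricated fit.

**Inverse and calibration.** `invert_probit` is closed-form
(`j = μ − s·Φ⁻¹((p − g)/(1 − g − l))`); targets outside the open asymptote
interval raise a range error naming the feasible interval.
`calibrate_levels(fit, 0.95, 0.50, 6)` produces the equidistant
percent-correct ladder {95, 86, 77, 68, 59, 50}% and its jitters.

**d′ transform.** Per level, PC is clipped to `[1/(2N), 1 − 1/(2N)]` and

    d′ = 2 · Φ⁻¹(PC)

(the unbiased single-interval two-alternative convention; a yes/no convention
`Φ⁻¹(H) − Φ⁻¹(FA)` is available as `dprime_yes_no`).

**Behavioral slope.** OLS of `log d′` on `log jitter`; levels with
d′ ≤ 0 have no logarithm and are dropped with a warning.  The report includes
β₀, β₁, residual σ (df = n − 2), and the t-based 95% CI for β₁.

## 3. Synthetic data (`veplink.synth`)

**Behavior.** `ObserverSpec` holds per-condition probit parameters and the
session schedule (6 jitter levels {1, 13.8, 26.6, 39.4, 52.2, 65}°, 432
trials/block = 72 per level, 2 blocks/condition, ISIs from {500…650} ms,
lognormal RTs with mean ≈ 820 ms, SD ≈ 119 ms).  Per trial, orientation is
balanced, correctness is Bernoulli with the probit probability, and the
response is derived from orientation × correctness.

`implied_dprime_slope` returns the (β₀, β₁) of log d′ on log jitter implied
analytically by an observer's probit parameters (expected-PC transform,
mirroring the estimation path's drop rule).  It agrees with the mean of
estimated slopes **when the observer's accuracy stays above chance at every
level**; observers at chance at the top level produce clip-dominated,
ill-defined log d′ there, which is why the linking test scenarios use an
observer (threshold 55°, scale 12) that spans the levels without touching
chance.

**Montage.** Fibonacci-spiral layout on the upper unit hemisphere; adjacency
joins pairs within a distance threshold widened automatically until the
median neighbour count is in [4, 10].  `contiguous_channel_set` grows a
connected channel set breadth-first — use it to plant effects whose ground
truth is a single spatial cluster.

**Epochs.** Per trial, the signal is a sum of:

- spatially correlated Gaussian noise (exponential distance kernel on the
  montage, SD 0.8) plus white noise (SD 0.6);
- evoked **components**: mean-centred Gaussian spatial bump × Gaussian time
  kernel, with a per-subject latency offset drawn once per subject (this is
  the peak-alignment rationale: components are reliable within subject but
  not time-locked across subjects);
- a planted **jitter effect** (below);
- an optional **class signal**: a zero-mean spatial bump added with a sign
  given by the stimulus orientation (mean-balanced, so it is invisible to the
  average and to the slope regression but decodable).

All topographies are mean-centred across channels, so the average reference
leaves them intact.

**Planted rectified-slope calibration.** The ground truth of the linking
analysis is defined *on the analysis scale*: after average reference,
per-subject global z-scoring, and rectification, the expected rectified
amplitude at effect points should be

    E|x| = sd_pool · (baseline + slope · log j).

To plant this exactly, the generator solves, per channel and jitter level,
`E|μ + ε| = target` for the signed mean μ (Brent root-finding on the folded
normal mean, with σ the post-average-reference noise SD of that channel), and
computes `sd_pool` — the pooled SD the z-score step will divide by — by a
fixed-point iteration over the analytic second moment of the composite
signal.  Channel gains alternate in sign across the effect channels so the
planted means cancel in the cross-channel average (average-reference
invariance).  Infeasible targets (below the folded-normal noise floor,
e.g. a steep slope with a small baseline) raise an explicit error rather than
silently planting a distorted effect.  `GroundTruth` records masks, slopes,
per-subject component latencies, the class topography, and the pooled SD.

## 4. Neurometric linking (`veplink.neurometric`)

**Preprocessing** (fixed order, each stage toggleable):
average reference → per-subject z-score with one mean/SD over all
trials × channels × timepoints → rectification (absolute value).

**Slope maps.** Per subject and per (channel, timepoint), the OLS slope of
single-trial rectified amplitude on log jitter (raw-jitter mode available).
Implemented as vectorized centred cross-products, verified bit-equivalent to
per-point OLS.  Log jitter is the default in *both* the EEG and behavioral
regressions because the CI-matching step presumes commensurate slopes.

**Cluster-based permutation.** One-sample t across subjects at each point;
points with |t| above the two-tailed cluster-forming quantile (p < 0.01,
df = S − 1) are clustered under spatial adjacency × temporal contiguity with
equal sign; cluster mass = Σ|t|.  The null is the distribution of the maximum
cluster mass **over both signs** under random per-subject sign flips
(Σx² is flip-invariant, so permuted t-maps reduce to a matrix product);
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`.  Clusters with p ≤ 0.01 are
significant by default; both the forming threshold and the cluster α are
configurable and logged.

**Behavioral-CI matching.** The behavioral CI is the t-based 95% CI of the
mean of per-subject β₁ (primary mode) or a pooled fit's CI.  A point inside a
significant cluster is retained iff the cross-subject mean EEG slope at that
point lies inside the CI (point-wise mask); a cluster-level variant retains
whole clusters whose cluster-average slope is inside the CI.  Both are
reported; the match mask is always a subset of the significant clusters.

**Response locking.** `relock_to_response` re-centres each trial's window on
stimulus onset + RT (nearest sample); trials whose window leaves the epoch
are dropped with a logged count.  With RT spread ~120 ms, a stimulus-locked
effect smears across response-locked time: it may still reach significance as
a diluted cluster, but its attenuated slope no longer falls inside the
behavioral CI — the match mask comes back empty (the package's null-pattern
demonstration).

## 5. Components (`veplink.components`)

Per subject, the grand average over all conditions and levels selects, within
each search window, the electrode with the largest mean |amplitude| (signed
modes for N/P components); the latency of the in-window extremum at that
electrode is the subject's component latency; amplitudes are read out there
for each condition × level cell.  Boundary extrema (flat/monotone signal) are
flagged and excluded from modelling.

The peak-amplitude model is a random-intercept-per-subject linear model
(maximum likelihood, so LRTs on fixed effects are valid) of amplitude on
log jitter × condition, simplified backwards: full → drop interaction → drop
condition → drop jitter, stopping at the first significant LRT (α = 0.05),
with a condition-only branch tested when the chain reaches intercept-only.
When the between-subject variance sits on the zero boundary (singular
Hessian), the fit falls back to plain ML regression, with which it coincides
there.  Note the chain's family-wise property: under pure noise the
intercept-only model is selected with probability (1 − α)⁴ ≈ 0.815, not
1 − α; the acceptance suite checks this rate as a calibration band rather
than pretending the chain has level α.

## 6. Decoding (`veplink.decoding`)

Class balancing down-samples the majority orientation to the minority count
(seeded), once before cross-validation.  The shrinkage coefficient γ is the
OAS (oracle-approximating shrinkage) estimate of the channel covariance at
each timepoint, averaged over timepoints and then subjects.  At each
timepoint an LDA with covariance `(1 − γ)·Σ̂ + γ·(trΣ̂/C)·I` is evaluated
with stratified 10-fold CV; weights come from a full-data fit, and activation
patterns are `Σ̂·w` normalized to unit maximum absolute value (the forward
model of the discriminant).  Significance of the group accuracy time course
vs chance uses the 1-D analogue of the sign-flip cluster permutation test.

## 7. Problem sizes and defaults

The acceptance suite runs scaled-down versions of the analyses so that the
full test suite completes on one CPU within minutes: 32 channels instead of
128, 500 permutations instead of 5000, 120 timepoints, 16 subjects.  Scaling
affects power and runtime, not the validity of the calibration checks.  Null
datasets for permutation-test calibration are generated directly at the
statistic-map level (i.i.d. Gaussian, a sign-symmetric null — exactly the
exchangeability condition the sign-flip test requires).

## 8. Limitations

- The EEG generator is a statistical stand-in (correlated Gaussian noise,
  Gaussian bumps), not a biophysical forward model; no artifacts, no 1/f
  shaping beyond the spatial kernel.
- Latency variability is per-subject constant, not per-trial.
- Class balancing happens once before CV; the leakage-free alternative
  (balancing within folds) is noted but not implemented.
- The probit fit uses multistart local optimization; identifiability is
  checked only for the flat ceiling/chance cases.
- Linking scenarios require observers whose accuracy stays above chance at
  every level; at-chance levels make log d′ clip-dominated (see §3).
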