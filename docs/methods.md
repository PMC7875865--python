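# Methods

## Model

A scanpath is an ordered sequence of fixations, each reduced to its 2D pixel
coordinates. For one observer group on one image, all subjects' sequences are
pooled and modelled by a hidden Markov model λ = (A, B, π) with N hidden
states: π is the initial state distribution, A the N×N row-stochastic
transition matrix, and B assigns state k a bivariate Gaussian over pixel
coordinates with mean μ_k and, by default, a diagonal covariance
diag(σ²_kx, σ²_ky). Hidden states are interpreted as attraction regions of the
image (primes, targets, distractors, broad orientation); transitions between
states are the saccades between those regions. Each sequence independently
starts from π, and E-step statistics accumulate across sequences — the only
convention consistent with pooling all subjects of a group into one model
while keeping per-subject scanpaths intact.

Assumptions worth stating: fixation coordinates within a state are
conditionally independent given the state (no within-state drift), the state
process is first-order Markov and time-homogeneous, and fixation durations
carry no information for the model (they are kept in the data model as an
extension point but are not emission features).

## Estimation

Unconstrained Baum–Welch EM. The forward–backward recursions run in scaled
arithmetic with a per-frame shift of the emission log-densities, so
likelihoods remain finite for sequences up to 10⁴ fixations even when a
fixation lies hundreds of SDs from some state's mean. The inner recursions are
numba-compiled. Numerical choices:

- **Initialisation.** Default `kmeans`: emission means at k-means cluster
  centers of the pooled coordinates, per-cluster variances. Restarts use
  `random`: means drawn from observed fixations, pooled variance split across
  states. A starts with self-transition δ = 0.8 and the remaining mass
  uniform (fixation sequences are strongly persistent); π starts uniform.
- **Variance floor.** 1 px² per axis, enforced every M-step, preventing a
  state from collapsing onto a single fixation. For full covariances the
  cross term is additionally capped below the geometric mean of the axis
  variances to keep the matrix positive definite.
- **Convergence.** Relative log-likelihood improvement < 1e-6 or 500
  iterations. The recorded trace is non-decreasing up to 1e-8 (EM
  monotonicity; the floor can in principle break it, but never does on the
  suite's data).
- **Minimum data.** A fit requires at least 5 fixations per state; scans
  skip infeasible attempts and report an error only if every restart of some
  N fails.
- **Ties.** Posterior argmax and Viterbi both break ties toward the lower
  state index (strict comparisons), making decoded assignments deterministic.

Degenerate likelihood evaluations (all forward mass dying at a step, possible
only when transition structure traps mass in a state whose emission underflows)
raise a dedicated error carrying the EM iteration.

## Order selection

State counts 2–14 are fitted per group × image (defaults; any range ≥ 1 is
accepted), keeping the best of 3 seeded attempts per N (first attempt k-means,
restarts random). Seeds derive deterministically from a base seed and the
(N, attempt) pair via `numpy.random.SeedSequence`, so any recorded attempt can
be reproduced exactly. Because an N-state model nests every (N−1)-state model,
the attainable log-likelihood is non-decreasing in N; an observed drop is
operationalised as a *discontinuity* (logL(N) < logL(N−1)) and repaired by up
to 4 rounds of 5 additional random-start attempts at the offending N, never
discarding a better fit (hence idempotent). Remaining discontinuities — which
occur occasionally at large N on small cohorts — are flagged, not fatal. The
selected model minimises BIC = −2 logL + k ln n with n the pooled fixation
count and k = N² + 4N − 1 free parameters for diagonal emissions
(N² + 5N − 1 full): (N−1) for π, N(N−1) for A, 2N means, 2N (or 3N)
covariance terms.

## Precision

Each fixation is classified exhaustively and disjunctively to one state;
smoothed-posterior argmax is the default (Viterbi optional) since group-level
interpretation concerns marginal membership, and the choice is exposed because
either decoding is defensible. States are cross-tabulated against AOI labels
(polygon membership by the even-odd rule, boundary points inside; everything
outside the labelled polygons is white space). Each prime/target AOI links to
the state with the most of its fixations (ties to the lower index; many-to-one
allowed — frequent transitioning between nearby AOIs can merge them into one
state, and the linkage reproduces that case). Precision of AOI a with linked
state s is 100 · #(fixations in s and inside a) / #(fixations in s). Per-subject
precision restricts both counts to one subject while keeping the group-level
linkage — the reading consistent with group-level models feeding a
per-subject ANOVA. A subject with no fixations in the linked state scores 0
and is flagged; an AOI with no fixations anywhere has undefined linkage and is
omitted with a flag. White space is never linked; states linked to no AOI are
reported as distractor/orientation states.

Touch scoring: a target is identified when any touch lies within an inclusive
50 px Euclidean radius of its center, each target at most once.

## Group statistics

Welch's t from group summaries (mean, n−1 SD, n), Welch–Satterthwaite df,
two-sided Student-t p. The precision ANOVA is the univariate split-plot
decomposition for a balanced design: one between-subjects factor (group) and
two within factors (image, AOI position 1–3); the between effect is tested
against subjects-within-groups, each within effect and its group interaction
against the matching subject-interaction stratum. No sphericity correction is
applied and unbalanced tables are rejected with the missing cells listed —
a multivariate repeated-measures route would change the within-effect df and
was deliberately not taken, because the univariate decomposition is fully
reconstructible and is verified in the suite against R's `aov` error
stratification and by Monte-Carlo type-I calibration (≈5% at α = 0.05). No
multiple-testing correction is applied anywhere.

## Synthetic data

The generator emulates a tablet visual-search task: a 1920×1200 canvas, three
140 px primes stacked in a right-hand band, three targets placed disjointly in
the image field. The ground-truth HMM has one state per AOI (SD 45 px), one
state per requested distractor, and a broad orientation state over the canvas
(SD ≈ 22% of each canvas extent); self-transitions 0.8, an extra 0.08 of
prime_k → target_k mass, and π half-weighted on the orientation state. With no
distractors this is a 7-state arrangement. Group presets encode the expertise
contrast: experts get AOI emission SDs ×0.6, two extra fine-grained states and
+0.06 AOI self-transition; novices get SDs ×1.5 and +0.10 transition mass onto
the orientation state. Fixation durations are lognormal with median 280 ms
(σ = 0.4) and sequence lengths lognormal with median 120 fixations (σ = 0.45,
clipped to [40, 350]) — scale-realistic magnitudes for this class of task; the
lognormal shape is the module's choice. Coordinates are clipped (not
rejection-sampled) at canvas edges; at the stated SDs the bias is negligible.
Touches land near target centers with a group hit probability (defaults
0.95/0.90) and 15 px scatter; completion time is summed fixation durations
plus 1.2 s motor overhead per touch. Every generator is a pure function of
(config, seed).

What the generator does **not** emulate: image-content/saliency-driven gaze,
center bias, oculomotor constraints on saccade amplitudes, measurement noise
of a mobile tracker, or between-subject heterogeneity beyond the sequence-
length and duration distributions. Passing tests therefore demonstrate that
the estimation, selection, linkage and statistics machinery recovers known
structure of this generative class — not that real recordings satisfy the
model's assumptions.

## Problem sizes in the validation suite

The suite and the acceptance script scale simulations to desk size as the
package's own test design: parameter recovery uses 30 sequences × 100
fixations; order-recovery experiments use 15 × 80 with scans over 2–10 and
10 replicates per true order (3, 5, 7); the end-to-end group contrast uses
6 subjects per group, one image, ~100 fixations per scanpath, scans over 2–14,
and 10 (suite) or 5 (script) seeds; ANOVA calibration uses 1000 null
simulations of a 2 × 6 × 3 × 3 design. Each reported quantity records the
problem size it was computed at.

## Visualisation

Per-state densities are Gaussian-kernel sums (default bandwidth 30 px, grid
step 4 px — legibility vs. cost) evaluated via the separable-kernel
factorisation and normalised per state; empty states yield zero grids flagged
as empty. The pooled heatmap optionally weights fixations by duration. A
state's "relative time of attendance" is approximated by its mean normalised
fixation onset (onset / subject task duration); this is documented as an
approximation, not asserted as a formal definition. Rendering (contours +
AOI outlines, PNG) is deterministic and never mutates the grids.

## Known limitations

- Only 2D coordinates are emission features; durations and saccade lengths
  are carried in the data model but unused by the HMM.
- The split-plot ANOVA requires complete balanced tables; missing cells must
  be handled upstream.
- BIC order recovery is demonstrated for well-separated truths; heavily
  overlapping attraction regions can legitimately select fewer states than
  the generative count.
- Discontinuity repair is best-effort; on small cohorts the 2–14 scan may
  retain non-monotone log-likelihoods at large N (flagged in the scan).
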