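# Methods

## Generative model

At each trial `t` a mode `z_t` is drawn from a sticky Chinese
restaurant process: an existing mode `k` with unnormalized weight
`N_k + β·1[z_{t-1}=k]` (`N_k` = trials previously assigned to `k`), a
new mode with weight `α`.  With `β = 0` the induced partition law is
the plain CRP; with `α = 0` exactly one mode is ever created and the
model collapses to a linear-Gaussian state-space model.  A new mode's
per-dimension state is drawn from `N(m0, c)`; every created mode's
state — active or dormant — diffuses once per trial as
`x ← λx + N(0, q)`; the observation adds sensory noise `N(0, r)`.
Covariances are diagonal throughout: dimensions share the mode
assignment (likelihoods multiply across dimensions) but carry
independent Kalman gains.

Mode labels are assigned in order of first appearance (each new label
is 1 + the running maximum), so partitions compare deterministically.

### Parameters

| symbol | meaning | units | default | notes |
| --- | --- | --- | --- | --- |
| `α` | concentration: propensity to open new modes | — | model-specific | 0 ⇒ single mode |
| `β` | stickiness: persistence of the active mode | — | 0 | adds to the previous mode's CRP weight |
| `q` | per-dimension diffusion variance | stimulus-units² | — | 0 ⇒ stationary mode states |
| `r` | per-dimension sensory-noise variance | stimulus-units² | — | likelihood width of each mode |
| `v` | per-dimension response-noise variance | stimulus-units² | — | behavioral read-out only; never enters the filter |
| `λ` (`decay`) | state decay per trial | — | 1 | 1 = pure random walk |
| `m0` | new-mode prior mean | stimulus-units | 50 per dim | center of the [0, 100] task space |
| `c` | new-mode prior variance | stimulus-units² | 1000 | approximately uniform over starting points |

## Inference: the local-MAP approximation

Exact posterior inference would marginalize over all partitions; the
DP-KF instead maintains a single high-probability partition.  Each
trial is scored against every instantiated mode and the potential new
mode by `log CRP-prior + log N(y_t; μ_pred, σ²_pred + r)` (summed over
dimensions, computed in log space and normalized with log-sum-exp, so
prediction errors up to ~10⁴ stimulus units cannot underflow).  The
trial is hard-assigned to the argmax — ties break toward the lowest
label, and an existing mode beats the new mode at exact equality
(parsimony) — and only the assigned mode is updated.  The assignment is
never revisited.  Dormant-mode growth is realized lazily: a mode
predicted after a gap of `Δ` trials has mean `λ^Δ μ` and variance
`λ^{2Δ} σ² + q·(Δ if λ=1 else (1−λ^{2Δ})/(1−λ²))`, the exact `Δ`-fold
composition of the per-trial dynamics.  The never-instantiated new mode
is scored at the base measure, predictive variance `c + r` (no
diffusion step before a first emission).

### Behavioral-prediction conventions

What counts as "the model's prediction" before seeing `y_t` is
genuinely underdetermined; three read-outs are implemented:

- **mixture** (default, used for fitting): the CRP-prior-weighted mean
  over instantiated modes plus the new-mode term at `m0`.
- **map**: the predicted mean of the a-priori most probable mode.
- **assigned** (recorded in every trace as `assigned_pred`): the
  predicted mean of the mode the trial is eventually MAP-assigned to —
  the quantity one plots when coloring predictions by assignment, and
  the read-out used by the jump demonstration.  Note the count-dominated
  CRP prior keeps most weight on an old mode for many trials after a
  jump, so the mixture read-out cannot "catch up" in one trial even
  when segmentation is instant; the assigned read-out reflects the
  segmentation itself.

For `α = 0` all three coincide with the classical Kalman-filter
prediction (verified to 1e-10 against an independently coded textbook
filter).

## Reconstruction by within-mode smoothing

Retrieval of trial `t` takes the MAP partition as fixed, re-filters the
probed mode's observation chain, and runs the Rauch–Tung–Striebel
backward recursion `x̂_{i|T} = x̂_{i|i} + J_i (x̂_{succ|T} − λ^Δ x̂_{i|i})`
with `J_i = λ^Δ σ²_{i|i} / (λ^{2Δ} σ²_{i|i} + q_Δ)`, where gaps in the
chain accumulate diffusion exactly as in filtering.  Observations
assigned to other modes are invisible to the reconstruction (verified
by perturbation).  Retrieval noise adds a constant (default 5
stimulus-units²) to `r`; it is applied to **both** the re-filtering and
the backward pass (`where="both"`), the internally consistent choice —
`where="backward"` is available since the alternative convention is
defensible.  With `q = 0` smoothing collapses to the conjugate
posterior of a constant state (precision-weighted average of the
chain's observations with the prior), the maximal-interference limit.

## The behavioral task generator

Blocks hold 18 stimuli in the standardized [0, 100]² (orientation,
length) space.  Every transition is a 45° move of ±5 units per
dimension; jump blocks replace the transition between trials 9 and 10
with a ±20-unit (4×) move.  No transition may exactly reverse its
predecessor, and the start-to-end Euclidean distance must lie in
[0.60, 0.70] of the diagonal in both conditions.  The step size of 5
units is chosen so 17 steps can span the required band (17·5·√2 ≈ 120
≥ 0.70·141.4); it is a config knob (`TaskGeometry`).

The band constrains trajectories severely — 13 to 17 of the 17 steps
per dimension must share a sign — so the generator is constructive: it
enumerates once the admissible per-dimension net displacements (odd
lattice points for gradual blocks; even points plus the signed jump for
jump blocks), samples one, shuffles the step order (re-shuffling on a
backtracking violation), and places the start uniformly in the interval
that keeps the path inside the space.  Because the worst-case path span
is 85 units (gradual) or 100 (jump), a feasible start always exists;
an impossible geometry raises a diagnostic error.  The admissible-set
construction makes the two conditions' start-to-end distances match by
design (both sampled from the same band; the discrete lattices differ
by under half a pooled standard deviation).

Sessions interleave 6 gradual and 6 jump blocks at random; the
reconstruction probe is uniform over trials {1, 2, 3} (its true
distribution is unknown).  Whether trial 1 (no information) is a real
prediction is likewise unknown: trial-1 responses are generated from
and scored against the prior mean `m0`, with a switch
(`include_trial1=False`) to drop them from likelihoods.

## Synthetic participants and cohort calibration

A synthetic participant reports the model's mixture prediction on every
trial and its smoothed reconstruction at the probe, each corrupted by
`N(0, v)` per dimension.  The cohort default
(`task.DEFAULT_AGENT`: α=0.05, β=15, q=2, r=18, v=4, λ=1) was selected
by mechanism, not by any downstream test statistic, using three
closed-form quantities and a small simulation grid:

- tracking: the steady one-step lag on the task's ±5 drift is
  `step/η` per dimension with `η = S/(S+r)`, `S = (q+√(q²+4qr))/2`;
- segmentation: a new mode opens when the error norm exceeds roughly
  `σ_pred √(2[ln((N_k+β)/α) + 2 ln(σ_new/σ_pred-ratio)])`;
- interference reach: future observations influence a smoothed estimate
  through per-step factors `J = P/(P+q)` with `P ≈ η_s (r+5)`.

These trade off — long interference reach (small `q/r`) inflates the
tracking lag toward the segmentation threshold.  The chosen values are
the regime where gradual blocks stay (mostly) one mode (~10% acquire a
second), the 4× jump splits ~90% of jump blocks, and smoothing reaches
far enough backward that post-jump trials measurably distort a gradual
block's early memories.  This is the regime the model is *about*; far
outside it the conditions do not differ and the behavioral analyses are
uninformative.  Synthetic agents emulate trial/block structure,
response noise and the model's own decision process — not human lapses,
motor error anisotropies beyond Gaussian `v`, learning across blocks,
or any deviation from the model family, so passing tests show internal
consistency and recoverability, not that humans behave this way.

## Model variants and fitting

Four nested variants: stationary KF (α=0, q=0; 5 free parameters:
v¹, v², r¹, r², λ), KF (+q¹, q²; 7), stationary DP-KF (+α, β over the
stationary base; 7) and the full DP-KF (9).  The decay λ completes the
counts and is bounded [0.25, 1]; a `fit_decay=False` switch pins λ=1,
reducing the counts by one.  `m0` is fixed at (50, 50) and `c` at 1000.

Fitting minimizes the negative log-likelihood of prediction-trial
responses under `N(prediction, v)`.  Box bounds: `v ≤ 10`, `q ≤ 30`,
`r ≤ 20` (upper), variances ≥ 1e-3, `α ∈ [0, 10]`, `β ∈ [0, 20]`.
Because the filter's predictions never depend on `v`, the optimal
`v_d` is the clipped mean squared residual and is profiled out; the
bounded Powell search (tolerances 1e-6, appropriate for the
piecewise-smooth objective created by hard assignments) therefore runs
over 3–7 dimensions, from 3 starting points drawn uniformly in the box.
Nested-model comparisons additionally warm-start each variant from its
best-fitting restricted sub-model, which protects the nesting
inequality `NLL(dpkf) ≤ NLL(kf) ≤ NLL(stationary_kf)` from local
minima.  The fitting inner loop runs through a numba kernel
(`dpkf._fast`) equivalence-tested against the reference filter at
1e-10.  Reconstruction trials are excluded from every fit; they are
scored afterwards under the fitted parameters with the retrieval-noise
constant, and an even/odd block split provides cross-validated
predictive log-likelihoods.

Within-subject error bars use the Loftus–Masson/Morey normalization
(subject means removed, small-cell correction √(c/(c−1))); the 2×2
(first/last × gradual/jump) interaction is a repeated-measures ANOVA on
subject-level cell means (2-level factors, so no sphericity issue),
cross-checked against hand-computed sums of squares.

## Demonstration simulations

**Jump demo** (`JumpDemoConfig`): a 1-D ramp of 0.5/trial over 30
trials with a +8 jump at the midpoint, observed with `r = 1`; DP-KF
(α=1, β=0, q=0.2) vs. KF (α=0) on identical noise, 100 runs.  `q=0.2`
keeps the ramp's steady lag (≈1.4) well below the new-mode threshold
(≈4) so the pre-jump phase stays in one mode.  The catch-up lag is the
number of trials after the first post-jump observation until the
one-step absolute prediction error (assigned read-out) falls below the
pre-jump median (trials 2..15) — an operationalization of a qualitative
description.

**Morph demo** (`MorphDemoConfig`): 20 morphs on [0, 1] presented in
gradual or scrambled order, 100 runs, with noise scales matched to the
unit interval (r=0.005, q=0.002, m0=0.5).  The reported posterior curve
is that of the *low-anchor* mode — the mode MAP-assigned to morph 0 —
which for gradual runs is simply mode 1; in scrambled runs the first
stimulus is an arbitrary morph, so anchoring is what makes runs
averageable.  Dominant-mode count = modes holding majority posterior at
some position (majority over runs); the transition point is where the
run-averaged anchor curve first drops below 0.5 after re-sorting.

## Numerical conventions and problem sizes

All randomness flows through caller-supplied `numpy.random.Generator`s;
inference itself is deterministic and bit-reproducible.  Trials and
mode labels are 1-based in public APIs and serialized tables.
Degenerate inputs (empty sequences, non-finite observations, negative
counts, unknown protocols/modes, empty block subsets, zero-variance
correlations) raise `ValueError`; an unsatisfiable task geometry raises
a diagnostic generation error.  Study sizes follow the designs above:
100-run demos, 20-participant cohorts with full 12-block sessions, and
a 10⁴-blocks-per-condition generator audit.

## Known limitations

- The local-MAP partition cannot revise early assignments; regimes with
  ambiguous early evidence can lock in a suboptimal segmentation that a
  particle filter would escape.
- The likelihood surface is piecewise-smooth in the hyperparameters
  (assignment flips), so fitted optima are local by construction;
  restarts and warm starts mitigate but cannot guarantee global optima.
- α and β are only weakly identified from 12 blocks of data (they enter
  through a handful of assignment decisions); `v` and `r` recover well,
  α recovers in sign and order of magnitude.
- With λ < 1 states decay toward 0, not toward `m0`; fitted λ near the
  upper bound is expected for stimuli centered mid-space.
- The task generator samples uniformly over the admissible
  net-displacement lattice, which is a (deliberate, documented)
  distributional choice the original step-wise procedure leaves
  implicit.
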