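# Methods

`affectdyn` implements a framework for characterizing affect-processing
dynamics in the task-free brain: resting fMRI is projected into a
low-dimensional affective state space (valence, arousal) by neural decoding
models trained on task data, the temporal derivatives of the decoded
trajectories are themselves decoded from brain states (a neurally
constrained ODE), and the ODE is validated by closed-loop simulation
against a temporally scrambled surrogate. This note documents the models,
the synthetic data the package is validated on, and the numerical and
design choices that were genuinely open.

## Decoding models of affect

**Brain states.** Single-trial activation estimates come from beta-series
regression in its least-squares-separate (LSS) form: for each trial a GLM
is solved containing (i) the HRF-convolved regressor of that trial, (ii) a
single regressor summing all other trials, (iii) Legendre drift polynomials
(orders 0–2 per run by default), and (iv) optional confound columns. The
trial-of-interest coefficient is that trial's beta. LSS preserves
trial-level variance where conventional averaging collapses it, at the cost
of a misspecification bias when trial amplitudes differ and regressors
overlap; the test suite pins down the regime in which LSS agrees with the
full per-trial GLM exactly (isolated trials, intercept-only baseline).
Convolution uses the canonical double-gamma HRF (response peak 6 s,
undershoot 16 s, peak:undershoot 6) sampled at the repetition time
(TR = 2 s); with 2 s stimuli, sub-TR microtime resolution adds nothing.

**Classifiers.** Normative 9-point Likert scores are binarized at the
midpoint (score > 5 → +1, else −1; exact ties go to −1 — with continuous
normative means, ties have measure zero) and a soft-margin linear SVM
(C = 1, solution tolerance 1e-3) is fit per subject and affect dimension.
Any convergent hinge-loss solver is acceptable; equivalence is at the
solution level, and symmetry properties (label flip ⇒ negated hyperplane)
hold to the solver tolerance.

**Validation.** Leave-one-out cross-validation with 30 class-balanced
subsamples of each training fold (majority class downsampled to the
minority count) keeps the null classification rate at exactly 50%
regardless of label imbalance. Accuracy is the mean over all
fold × resample predictions.

**Prediction.** New brain states are decoded as the signed geometric
distance to the hyperplane, (w·x + b)/‖w‖. Whether published hyperplane
distances are ‖w‖-normalized is ambiguous; we normalize so that ensemble
averages are commensurable across subjects, and note that every downstream
statistic (correlations, regression slopes, paired error comparisons) is
invariant to any common positive rescaling per model.

## Resting-state decoding

A resting run has no events, so "self-task" stimuli are planted at volume
acquisition times: each of 30 iterations samples 100 distinct volume times
uniformly (without replacement within an iteration) from the decodable
window — the first 5 and final 10 volumes are discarded — and the
beta-series machinery turns each onset into a brain state. Each state is
decoded by the ensemble average over the state classifiers of all *other*
subjects (out-of-sample purity is asserted from model metadata). Grouping
decodings by volume across iterations yields a per-volume mean with a
t-based 95% CI.

Gross outliers are screened per dimension by median/MAD statistics: x is
flagged iff |x − median| / (1.4826·MAD) exceeds the two-sided Gaussian
quantile at α/n (α = 0.05, Bonferroni over the n finite values). The
literature this rule follows specifies the screening statistics but not
the exact threshold; the Bonferroni-corrected Gaussian z is our
operationalization. A zero MAD with non-constant data would flag every
off-median value, so the screen disables itself with a warning in that
degenerate case. Flagged volumes become NaN and stay NaN everywhere
downstream.

## Dynamics and the neurally constrained ODE

Derivatives of the outlier-corrected decoded series use center divided
differences in volume units — dx/dt[t] = (x[t+1] − x[t−1])/2, and the
second derivative is the same stencil applied to the first-derivative
series (an effective 5-point stencil of x). There is no hidden TR
rescaling; one "time unit" is one volume (2 s). NaNs propagate through the
stencil and endpoints are NaN.

Per-volume brain-state features for derivative decoding are the
across-iteration mean self-task betas — the same estimates underlying the
state decoding. The source publications do not state whether single-draw
betas or aggregates are used; the mean is the lowest-variance choice
consistent with training "directly on the derivatives". Linear ε-SVR
(C = 1, ε = 0.1 × target SD, tolerance 1e-3) maps features to each
derivative target, dropping NaN rows. Out-of-sample validation is
leave-one-subject-out: the hold-out subject's derivatives are decoded by
the ensemble mean of all other subjects' models (a within-subject
leave-one-volume-out scheme is also provided).

## Closed-loop simulation and the surrogate null

From every volume with a finite decoded state and decoded first
derivative, the trajectory is integrated by forward differencing:
x[t+1] = x[t] + dx/dt[t], then dx/dt[t+1] = dx/dt[t] + d²x/dt²[t].
Position and velocity evolve closed-loop; the acceleration fed into each
step is the second derivative decoded from the brain state at the
corresponding *real* volume time. This is the only reading consistent
with integrating "the current x and dx/dt" while the decoders remain the
source of d²x/dt². Trajectories truncate at the first NaN acceleration.

The surrogate null uses the identical integrator but draws a (d1, d2)
pair uniformly *with replacement* from the subject's observed set at every
step (the first draw also replaces the initial velocity), destroying
temporal order while preserving the marginal distribution. Simulation
error is the absolute deviation between the simulated and the *decoded*
state ("true" means the decoded trajectory, not the latent one — on real
data no latent exists). Per subject and step k (k = 1..6), errors average
over all valid start volumes; the surrogate additionally averages over 30
resampling iterations (the true-sequence simulation is deterministic, so
iterations only affect the surrogate). Group inference is a two-sided
paired t-test per step; a degenerate comparison (all paired differences
zero) is reported as NaN with a flag.

Within-subject RMSE of the closed-loop first derivative versus the
numerically computed first derivative, as a function of step count, is
summarized by a robust linear growth model: iteratively reweighted least
squares with Tukey bisquare weights (tuning constant 4.685) per subject,
then a one-sample t-test of the subject slopes against zero with a t-based
95% CI.

## Encoding maps

Decoding weights are not activation patterns, so group maps use the Haufe
transform a = Σ_x w / (wᵀ Σ_x w): the forward-model pattern of a
unit-variance latent source. The scaling by the latent prediction variance
fixes one per-subject convention; group statistics are covariant to any
common positive rescaling, and published descriptions omit the scaling
entirely. Features entering the covariance are exactly the features used
to train each model (task betas for state classifiers, per-volume mean
rest betas for derivative regressors).

Group maps are voxelwise means across subjects with a one-sample t. The
null distribution refits each subject's model on independently permuted
targets (class counts are preserved automatically; degenerate permutations
are redrawn), Haufe-transforms it, and stores the group mean — 500
permutations at full scale, 99 at fixture scale. Voxelwise two-sided
significance uses the rank p-value (1 + #{|null| ≥ |obs|})/(n_perm + 1),
never exactly zero. Suprathreshold voxels are clustered under face-wise
(6-neighbor) 3-D connectivity; components below 20 voxels are removed and
survivors are labeled by decreasing size (ties by scan order, so labeling
is deterministic). Written stat maps show t inside surviving clusters and
0 elsewhere.

## Group validation model

The measure of interest is the numerically computed ("true") derivative of
the decoded series; the fixed effect is the neurally decoded derivative.
A linear mixed-effects model with subject-wise random intercepts and
slopes estimates the group slope (Wald test and CI). Adjusted R² for a
mixed model has no canonical definition; we report
1 − (1 − R²)(n − 1)/(n − k − 1) with k = 2 on pooled fitted-vs-observed
values (fitted values include the random effects) and a marginal variant
using the fixed effect only. A two-stage fallback (per-subject OLS slopes,
one-sample t) replaces the mixed fit when the random-effects covariance is
singular or the optimizer fails, and agrees with it in sign and
significance on well-conditioned data (tested).

## The synthetic cohort

No generative model of resting affect is known, so the test harness needs
one rich enough to exercise every pipeline stage without claiming
biological truth. Each affect dimension follows an independent damped
stochastic harmonic oscillator x'' = −ω²x − γx' + ε with piecewise-constant
forcing redrawn each volume, integrated exactly (matrix exponential per
volume interval), so state, velocity and acceleration series are the
analytic derivatives of the simulated path at volume times. Defaults:
ω = 0.3 rad/volume (≈42 s period at TR = 2 s — slow spontaneous
fluctuation), γ = 0.05 /volume (light damping; zero damping with nonzero
forcing is rejected as unstable), forcing SD 0.1. The oscillator is the
simplest process with non-trivial, decodable second-order structure.

Six unit-norm random voxel patterns encode state, first and second
derivative per dimension, scaled by amplitudes (1, 3, 8): derivative
encodings are distinct patterns and deliberately stronger than the state,
so the regime where second-order dynamics are more robustly encoded than
the state itself is realizable. Subject patterns are the group pattern
plus a perturbation (scale 0.2 by default). Neural amplitude time courses
are convolved with the canonical HRF, Gaussian noise (SD 0.5 in
percent-signal-change units) and random Legendre drift are added, and each
voxel is mean-centered. Task runs present ~2 s stimuli with uniform 2–6 s
inter-trial intervals; trial amplitudes are (score − 5)/4 with scores
drawn uniformly on [1, 9]², which keeps both binary classes populated
(the generator warns if a sampler produces a single class).

What the generator does *not* emulate: scanner artifacts, motion, slice
timing, spatial normalization, physiological noise structure, or any
nonlinearity between neural state and BOLD beyond HRF convolution. Passing
recovery tests on this cohort demonstrates that the estimation machinery
is correct and well-calibrated under its own assumptions — it does not
certify performance on real fMRI, where the decoding SNR and the validity
of the linear forward model are empirical questions.

## Problem sizes

The default ("reference") cohort used by the recovery tests holds 20
subjects on a 6×6×6 grid (≈136 voxels inside a spherical mask, real 3-D
geometry so cluster operations are exercised), 40 induction trials and 120
resting volumes per subject. The `fixture` pipeline preset (also used by
`scripts/acceptance.py`) runs 12 subjects at the same geometry with 99
encoding permutations; the full pipeline completes in a few minutes.
Null-calibration experiments use a 200-voxel grid with 99 permutations, so
discrete rank p-values below 0.05 occur at rate 4/100 under the null —
inside the binomial band the calibration test checks. These sizes are the
package's own desk-scale choices; all counts scale through configuration.

## Known limitations

- Decoded affect is in hyperplane-distance units. Published RMSE figures
  in Likert units imply an affine calibration between decoded distances
  and Likert scores that is not specified anywhere we can verify; we keep
  hyperplane-distance units and surface the discrepancy rather than invent
  a calibration.
- The LSS design for self-task stimuli (100 overlapping events in a
  ~120–225 volume run) is heavily collinear by construction; per-volume
  estimates are correspondingly noisy and only the across-iteration
  aggregation makes them usable.
- With 30 iterations over a 105-volume decodable window, nearly every
  volume is sampled in every iteration, so per-volume sample counts
  cluster near 30 and CIs are close to homoscedastic; sparser sampling
  would change that.
- The mixed-effects fallback reports pooled-OLS adjusted R², which is not
  identical to the mixed-model quantity it replaces; the `method` column
  makes the substitution visible.
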