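# affectdyn

**Resting-state affect processing dynamics from fMRI.**

The untasked brain is not idle: affective experience drifts from moment to
moment during rest. `affectdyn` maps whole-brain resting-state fMRI into a
two-dimensional affective state space — valence and arousal — using linear
SVM decoding models trained out-of-sample on affect-induction task data,
then asks whether the *dynamics* of that low-dimensional trajectory are
themselves encoded in the brain. It is aimed at researchers working on
MVPA decoding, resting-state dynamics and computational affective
neuroscience.

## What it computes

1. **Brain states.** Single-trial activation patterns via beta-series LSS
   regression (one GLM per trial: the trial's HRF regressor, a summed
   other-trials regressor, Legendre drift, confounds).
2. **Affect decoders.** Per-subject linear SVM classifiers of binarized
   normative valence/arousal (score > 5 → +1), validated by leave-one-out
   CV with class-balanced resampling (chance is exactly 50%).
3. **Resting decodings.** "Self-task" stimuli planted at randomly sampled
   volume times (100 onsets × 30 iterations) turn a task-free run into
   decodable brain states; each state receives the ensemble-average
   hyperplane distance (w·x + b)/‖w‖ over all *other* subjects' models.
   MAD-based outlier screening replaces gross values with NaN.
4. **A neurally constrained ODE.** Temporal derivatives of the decoded
   series by center divided differences,

       dx/dt[t] = (x[t+1] − x[t−1]) / 2,   d²x/dt²[t] = (dx/dt[t+1] − dx/dt[t−1]) / 2,

   and linear SVR decoders that predict those derivatives from the
   per-volume brain states.
5. **Closed-loop validation.** Forward-difference simulation
   x[t+1] = x[t] + dx/dt[t], dx/dt[t+1] = dx/dt[t] + d²x/dt²[t], with the
   acceleration decoded from the real brain state at each step, compared
   against a surrogate that draws derivative pairs at random from the same
   distribution (temporal order destroyed). Paired t-tests per step; robust
   (IRLS bisquare) RMSE-growth slopes.
6. **Encoding maps.** The Haufe transform a = Σ_x w / (wᵀ Σ_x w) converts
   decoders to interpretable activation patterns; group maps are tested
   against label-permutation nulls (two-sided rank p) with face-wise
   ≥20-voxel cluster thresholding.
7. **Group validation.** Mixed-effects models (random slope + intercept per
   subject) of true versus decoded derivatives.

A synthetic cohort generator (`affectdyn.synth`) produces multi-subject
datasets with known latent oscillator dynamics and known voxel encoding
patterns, so every stage is testable without any data download. See
`docs/methods.md` for the model details and design rationale.

## Worked example

Run the full pipeline on the bundled fixture preset (12 synthetic
subjects, 6×6×6 voxel grid, 40 induction trials, 120 resting volumes):

```bash
affectdyn all --preset fixture --seed 1 --out scratch/demo
```

or equivalently from Python:

```python
from affectdyn import fixture_preset, run_stage
run_stage("all", fixture_preset(master_seed=1), "scratch/demo")
```

Selected outputs (`scratch/demo/validate/validation_report.tsv`):

```
dimension  order  fixed_slope  ci_low  ci_high  p          r2_adj  n_significant
valence    1      1.090        1.051   1.130    <1e-200    0.936   12
valence    2      0.852        0.812   0.892    <1e-200    0.840   12
arousal    1      1.104        1.070   1.138    <1e-200    0.932   12
arousal    2      0.879        0.830   0.929    5.1e-268   0.805   12
```

The fixed slope is the group effect of the neurally decoded derivative on
the true (numerically computed) derivative — near 1 with a CI excluding 0
means the ODE decoders recover the dynamics of the decoded trajectories in
every subject. And `scratch/demo/simulate/group_tests.tsv` (step 1):

```
dimension  step  mean_true  mean_surr  t       p
arousal    1     0.180      0.659      -12.9   5.4e-08
valence    1     0.190      0.704      -10.8   3.4e-07
```

Closed-loop simulation driven by the *true temporal sequence* of decoded
derivatives incurs ~3.5× less error than the temporally scrambled
surrogate: the decoded dynamics carry real temporal structure, not just a
marginal distribution.

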