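# Methods

## Model and state

The network comprises 20 state variables: six LIP rate units and their six
Ornstein–Uhlenbeck (OU) input processes, two IT orientation units with two
OU inputs, two gated AIP accumulators and two thresholded motor units.
Unit activities are in kHz (so the motor threshold `theta = 0.0926` kHz is
92.6 Hz and the motor cap 0.150 kHz is 150 Hz); reported firing rates
multiply by 1000. Time is in ms with t = 0 at cue onset; the perceptual
input switches on at `P_delay` and the target/orientation inputs at
`P_delay + T_delay` (Heaviside steps, with H[0] = 1). The background input
`s_back` is applied unconditionally.

The six LIP receptive fields sit on the display ring
L1–R1–R2–R3–L3–L2–L1; mutual inhibition is `eta_lip` between 1-step
neighbors, `eta_lip * decay1` at 2 steps and `eta_lip * decay1 * decay2` at
3 steps. Left-facing targets drive the left IT unit, which drives the left
AIP unit and hence the left hand; bilateral symmetry is exact, which the
test suite verifies by mirroring states and conditions.

Design choices where the published description is open:

- **LIP leak.** The LIP rate equations are integrated as
  `tau_lip dX = (phi[...] − X) dt`, matching the IT form. A leak-free LIP
  (`EngineOptions(lip_leak=False)`) would make every LIP unit monotonically
  increasing (phi ≥ 0.001 > 0), which contradicts the decaying firing-rate
  profiles the model is meant to produce; simulations with the fitted
  parameters confirm the leak-free form destroys the behavioral fit.
- **Noise convention.** An equation written `tau dX = f dt + c xi(t)` is
  discretized literally: increment `(f/tau) dt + (c/tau) sqrt(dt) N(0,1)`.
  The OU inputs then have stationary mean equal to their drive and variance
  `c^2 / (2 tau)`, which a long-run simulation test confirms. The
  alternative `c/sqrt(tau)` scaling is available
  (`EngineOptions(noise_scaling="sqrt_tau")`) but produces noise-dominated,
  near-chance behavior with the fitted parameters.
- **Initial conditions.** All 20 state variables start at 0 at cue onset.
  The pre-cue placeholder period is not simulated (see Limitations).
- **Clamping.** The gated accumulators (AIP, motor) are clamped at 0 after
  every step and the motor units are capped at 0.150 kHz. Clamps are also
  applied to the Runge–Kutta predictor state: evaluating the drift at a
  (unphysical) negative activity would convert mutual inhibition into a
  spurious excitation of the opposite unit, which shows up as a slow
  threshold creep in zero-noise runs.

## Integration

Trials are integrated with a stochastic Heun scheme (second-order
Runge–Kutta for additive noise): one full-noise Euler predictor, drift
averaged over the two endpoints, the same noise increment added once.
`dt = 0.5` ms; halving dt moves zero-noise crossing times by < 1 ms.
Euler–Maruyama is available via `EngineOptions(scheme="euler")`.

The hot loop is a numba kernel with one RNG stream per trial; per-trial
seeds derive from the master seed, so batches are bit-reproducible. A pure
numpy implementation of the same drift lives in `model_core.drift` and the
two are cross-checked in tests. Trials end at the first motor threshold
crossing (response side = crossing unit; RT adds `T_0`) or at
`t_max = 1500` ms (timeout; excluded from accuracy/RT summaries but
counted). When trajectories are recorded, integration continues through the
recording window `[0, traj_t_max]` (default 800 ms, 1-ms sampling) even
after a crossing, so the averaged traces show the post-response suppression
of LIP/IT by motor feedback; without recording, crossed trials stop
immediately.

## Summaries

- Firing rates from spikes: each spike contributes a unit-area Gaussian
  (sigma = 15 ms, area in seconds so rates are in Hz); traces are averaged
  over trials (trial-weighted, not cell-weighted), with no boundary
  correction at the window edges.
- Cell filters: cells whose maximum smoothed trial-averaged rate exceeds
  80 Hz, or that lack trials at any of set sizes {2, 4, 6}, are excluded.
- RT quantile bins: edges at the 0.1/0.3/0.5/0.7/0.9 quantiles (type-7
  linear interpolation of order statistics), giving six bins with
  10/20/20/20/20/10% of the reference mass.
- Accuracy-vs-RT: 100-ms bins per (set size, congruence); empty bins are
  omitted rather than reported as 0%.
- Condition labels for model LIP units: the unit holding the target is
  "target in RF"; other stimulated units are distractors in the same or
  opposite hemifield; unstimulated units are excluded from comparisons. At
  set size 2 no same-hemifield distractor exists.
- Decision time: mean RT − (P_delay + T_delay + T_0).

## Objective and fitting

One objective evaluation simulates `n_sim` trials (default 6000) per
congruence condition — a right-facing target at R1 (congruent) or L1
(incongruent), which suffices because the parameters are hemifield-
symmetric — and computes

    alpha_FR * (1/(2 SS)) sum_cond sum_units sum_t ((FR_model − FR_ref)/max(FR_ref, 1 Hz))^2
      + alpha_corr  * (1/2) sum_cond chi2_correct
      + alpha_incorr * (1/2) sum_cond chi2_error

on a 1-ms grid over [0, 800] ms. The chi-square uses the reference sample's
quantile bins with model counts rescaled to the reference N and floored at
1.0; a correct/error class with fewer than 12 reference trials is skipped
(its rescaled single-bin statistic is identically zero). The FR term
compares per-label average traces; the reference denominator is floored at
1 Hz because rates approach 0 near cue onset. Model FR appears in the
numerator only — the relative error is taken against the reference trace.

Fitting holds the simulation seed fixed across objective calls (common
random numbers), making the objective deterministic; a reference bundle
generated from the same seed then has its exact minimum (zero) at the
generating parameters, which is the basis of the self-fit and
parameter-recovery tests. The optimizer runs an optional simulated-
annealing stage (scipy `dual_annealing`) followed by bounded Nelder–Mead in
coordinates scaled by the starting point, opened with a large initial
simplex (±45% per coordinate): quantile-bin counts change discretely as
parameters move, leaving jagged local barriers — the error-trial chi-square
especially, with only tens of error trials at moderate `n_sim` — and a wide
simplex steps over them where the default small one stalls. The joint
two-subject parameterization (18 shared + 13 × 2 = 44 free values) is
handled by `ParameterVector`; full 44-parameter refits are out of scope at
desk scale.

## Synthetic datasets

`synthetic_data.generate_dataset` emulates the structure of the task
recordings: one session per cell, one block per set size, conditions drawn
uniformly over displayed positions and orientations, behavioral outcomes
from model simulation, and spikes drawn as an inhomogeneous Poisson process
whose intensity follows the RF unit's simulated LIP rate (the model is a
rate model; Poisson spiking is the minimal stand-in that makes the
spike-facing analysis code testable). The recording window is
[−500, RT + 200] ms with zero intensity before cue onset. The on-disk
format is three CSVs (cells/trials/spikes) that round-trip losslessly.
What passing these tests does *not* show: real LIP spike trains are not
Poisson, have pre-cue baseline activity, and vary across cells; the
synthetic data shares only the rate profiles and table structure.

## Problem sizes and reproduced values

Test and acceptance runs use 6000 trials per congruence condition for
behavioral summaries (matching the published simulation size) and 1000 for
the reduced-scale parameter-recovery experiment (four free parameters —
`w_itaip`, `w_lipaip`, `beta_aiplip`, `s_lip` — recovered within 20%, in
practice within a few percent).

With the shipped fitted parameters the simulator reproduces, within
stochastic tolerance: M11's set-size-4 accuracy and mean RT and its
congruence effect (congruent faster and more accurate), M12's accuracy and
near-absent congruence effect, the decrease of peak LIP rates and of model
mean RT with set size (the latter is the model's known qualitative
departure from the observed slowing), target-above-distractor LIP rates,
and the decision-time decomposition.

## Known limitations

- **M12 mean RT runs ~60 ms high.** M12's deterministic trajectory peaks
  just below its motor threshold, so roughly 15% of trials miss the first
  activation wave and cross only later with noise assistance; this slow
  tail inflates the pooled mean (median ≈ 453 ms) relative to the published
  set-size-4 model mean of 470.1 ms. The distribution body, accuracy, and
  all qualitative effects match. The likely source is the unresolved
  pre-cue period: with placeholders driving LIP before cue onset the
  network would start partially charged and first-pass crossings would be
  more reliable. Simulating that period is excluded here because the
  published input schedule is defined only from cue onset.
- No LIP→IT feedback, no AIP receptive-field structure, no modeling of the
  search process itself; delays are condition-independent.
- The converter for the original recordings is limited to the documented
  three-table CSV layout.
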