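# covertsearch

A multi-area stochastic accumulator model of a covert visual search task,
implemented as a tested simulator and fitting package.

In the task, a monkey fixates a display of 2, 4 or 6 placeholders; at cue
onset one placeholder becomes a left- or right-facing E (the target) and the
rest become distractors. The animal reports the target's orientation by
releasing the left or right bar. The decision therefore couples *visual
selection* (find the target) with *action selection* (choose the hand), and
neurons in the lateral intraparietal area (LIP) reflect both.

## The model

Twenty coupled stochastic differential equations describe four interacting
areas (activities in kHz, time in ms, t = 0 at cue onset):

- **LIP** — six leaky competing accumulators `X_lip,j`, one per placeholder
  location (L1–L3, R1–R3), with mutual inhibition that decays with ring
  distance (`eta_lip`, `eta_lip_decay1`, `eta_lip_decay2`), recurrent
  self-excitation `alpha_lip`, and a saturating rate function
  `phi[I] = 0.001 + 0.352(I−0.384) / (1 − e^{−352(I−0.384)} + 3.52(I−0.384))`
  bounded in (1, 101) Hz. Each unit is driven by an Ornstein–Uhlenbeck
  filtered input `rho_lip,j` (tau = 5 ms) carrying a perceptual step `s_lip`
  (on at `P_delay`, to the displayed locations), a target step `s_tar` (on at
  `P_delay + T_delay`, to the target location), and a background `s_back`.
- **IT** — two mutually inhibiting orientation units with OU-filtered input
  `s_ori` switched on at `P_delay + T_delay`.
- **AIP** — two gated accumulators (gate `G[I, g] = max(I − g, 0)`), one per
  response side, integrating `w_itaip`-weighted IT drive plus
  `w_lipaip`-weighted same-hemifield LIP drive; AIP excites same-side LIP
  (`w_aiplip`) and inhibits the opposite side (`beta_aiplip`).
- **Motor** — two thresholded gated accumulators fed by AIP (`w_aipm`),
  capped at 150 Hz. The first to cross `theta` triggers the response;
  RT = crossing time + nondecision time `T_0`. Rising motor activity feeds
  back as global inhibition on LIP/IT (`beta_mitlip`) and AIP (`beta_maip`),
  resetting the network after the decision.

31 named parameters per subject; the two shipped parameter sets (`m11`,
`m12`) are the published fits for the two animals, of which 18 values are
shared and 13 are subject-specific (44 free values in a joint fit).

Fitting minimizes a composite objective: a relative squared error between
simulated and reference LIP firing rates over [0, 800] ms plus quantile
chi-square statistics (bins at the reference RT distribution's
0.1/0.3/0.5/0.7/0.9 quantiles) for correct and error RTs, in congruent and
incongruent hemifield conditions, with weights `alpha_FR = 0.25`,
`alpha_corr = alpha_incorr = 1`.

## Worked example

```python
from covertsearch import TrialCondition, load_params, simulate_batch

params = load_params("m11")
conditions = [TrialCondition(4, "R1", "E_right"),   # congruent
              TrialCondition(4, "L1", "E_right")]   # incongruent
batch = simulate_batch(params, conditions, n_per_condition=2000, seed=1)
for congruent, name in ((True, "congruent"), (False, "incongruent")):
    print(name, f"{100 * batch.accuracy(congruent=congruent):.1f}%",
          f"{batch.mean_rt(congruent=congruent):.1f} ms")
```

prints

```
congruent 96.8% 465.4 ms
incongruent 90.2% 534.9 ms
```

i.e. on congruent trials (target hemifield matches the responding hand) this
subject's strong LIP–AIP coupling yields faster, more accurate responses,
while on incongruent trials the LIP-driven and IT-driven pathways push
opposite AIP units, slowing and degrading the choice. More narrative scripts
live in `examples/` (batch simulation, firing-rate summaries, set-size
effects, objective evaluation and parameter recovery, synthetic spike
datasets), and a thin CLI mirrors them:

```sh
covertsearch simulate --params params_m11 --set-size 4 --n 2000 --seed 1
```

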