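"""Simulate a set-size-4 session and summarize accuracy and reaction times.

Runs 2000 trials per response-hemifield condition with the fitted M11
parameters: congruent trials put a right-facing E in the upper-right
receptive field, incongruent trials in the upper-left.  The printed
accuracy and mean RT (threshold-crossing time plus the nondecision time
T_0) show M11's hallmark congruence effect: congruent responses are faster
and more accurate.
"""

from covertsearch import TrialCondition, load_params, simulate_batch

params = load_params("m11")
conditions = [TrialCondition(4, "R1", "E_right"),   # congruent
              TrialCondition(4, "L1", "E_right")]   # incongruent
batch = simulate_batch(params, conditions, n_per_condition=2000, seed=1)

print(f"{'condition':<14}{'accuracy':>10}{'mean RT (ms)':>15}")
for congruent, name in ((True, "congruent"), (False, "incongruent")):
    print(f"{name:<14}{100 * batch.accuracy(congruent=congruent):>9.1f}%"
          f"{batch.mean_rt(congruent=congruent):>15.1f}")
print(f"{'pooled':<14}{100 * batch.accuracy():>9.1f}%"
      f"{batch.mean_rt():>15.1f}")
print(f"timeouts: {batch.n_timeouts} of {len(batch.trials)} trials")
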