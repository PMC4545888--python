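"""Set-size effects on firing rates and behavior.

With the set-size-4 fitted parameters held fixed, the stimulus schedule is
switched to 2, 4 or 6 displayed placeholders.  Mutual inhibition among LIP
units suppresses peak firing rates as more units activate; accuracy falls
with set size, while model mean RT *decreases* — the model's known
departure from the observed slowing.
"""

import numpy as np

from covertsearch import TrialCondition, load_params, simulate_batch
from covertsearch.summaries import TARGET_IN_RF, model_fr_traces

params = load_params("m11")
print(f"{'set size':>8}{'accuracy':>10}{'mean RT (ms)':>14}"
      f"{'peak target FR (Hz)':>21}")
for ss in (2, 4, 6):
    conds = [TrialCondition(ss, "R1", "E_right"),
             TrialCondition(ss, "L1", "E_right")]
    batch = simulate_batch(params, conds, 1500, seed=3,
                           record_trajectories=True)
    peaks = []
    for cond in conds:
        for tr in model_fr_traces(batch, cond).values():
            if tr.label == TARGET_IN_RF:
                peaks.append(tr.rate_hz)
    peak = np.mean(peaks, axis=0).max()
    print(f"{ss:>8}{100 * batch.accuracy():>9.1f}%"
          f"{batch.mean_rt():>14.1f}{peak:>21.1f}")
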