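"""Generate a synthetic spike/behavior dataset and run the cell filters.

Builds a small dataset in the layout of the task recordings — per-cell,
per-trial spike times aligned to cue onset plus behavioral records — by
simulating the model and drawing spikes as an inhomogeneous Poisson
process from each cell's receptive-field LIP unit.  Two pathological cells
are injected (one firing above the 80 Hz ceiling, one missing a set size)
and the inclusion filters remove exactly those two.
"""

from covertsearch import load_params
from covertsearch.sde_engine import EngineOptions
from covertsearch.summaries import filter_cells, fr_from_spikes
from covertsearch.synthetic_data import generate_dataset, inject_artifacts

params = load_params("m12")
ds = generate_dataset(params, n_cells=3, trials_per_block=10, seed=4,
                      options=EngineOptions(t_max=1200.0))
print(f"generated {len(ds.cells)} cells, {len(ds.trials)} trials, "
      f"{len(ds.spikes)} spikes")

trace = fr_from_spikes(ds.spike_trains(0))
print(f"cell 0 (RF {ds.cells.loc[0, 'rf_location']}): "
      f"peak smoothed FR {trace.rate_hz.max():.1f} Hz "
      f"over {trace.n_trials} trials")

bad = inject_artifacts(ds, n_hot_cells=1, hot_rate_hz=95.0,
                       n_missing_set_size_cells=1, missing_set_size=6,
                       seed=5)
kept = filter_cells(bad)
removed = set(bad.cells["cell_id"]) - set(kept.cells["cell_id"])
print(f"after injecting 2 artifact cells: {len(bad.cells)} cells; "
      f"filters removed cell ids {sorted(removed)} "
      "(the >80 Hz cell and the missing-set-size cell)")
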