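"""Surrogate spike/behavior datasets with the structure of the recordings.

The experimental dataset pairs, per recorded LIP cell, spike times aligned
to cue onset with behavioral records (set size, target location and
orientation, response side, correctness, RT).  This module generates a
synthetic dataset of the same shape: each cell is assigned one LIP unit's
receptive field, trials are simulated from the model, and spikes are drawn
as an inhomogeneous Poisson process whose intensity follows that unit's
simulated rate trajectory (in Hz).  The model itself is a rate model; the
Poisson layer is the minimal spiking stand-in that makes the spike-facing
analysis code (kernel smoothing, cell filters) testable.

Sessions hold one cell each and consist of blocks with a fixed set size;
target position and orientation vary uniformly at random across trials, as
in the task.  The recording window is [-500, rt + 200] ms around cue onset
(the model carries no pre-cue dynamics, so spike intensity is zero before
cue onset).

On-disk format: three CSV files (``cells.csv``, ``trials.csv``,
``spikes.csv``) that round-trip losslessly through :meth:`SpikeDataset.save`
/ :meth:`SpikeDataset.load`.  Users holding the original recordings can
adapt them by producing the same three tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import LIP_UNITS, ModelParameters, TrialCondition
from .sde_engine import EngineOptions, simulate_batch

__all__ = ["SpikeDataset", "generate_dataset", "inject_artifacts",
           "poisson_spikes"]

_ACTIVE = {2: ("L1", "R1"), 4: ("L1", "R1", "L2", "R2"), 6: LIP_UNITS}


@dataclass
class SpikeDataset:
    """Cells x trials spike-time dataset with behavioral records.

    ``cells``: cell_id, subject, session, rf_location.
    ``trials``: trial_id, cell_id, session, block, set_size, position,
    orientation, congruent, response_side, correct, rt_ms, timed_out.
    ``spikes``: cell_id, trial_id, spike_time_ms (cue-onset aligned).
    """

    cells: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame

    def subset(self, cell_ids: Sequence) -> "SpikeDataset":
        keep = set(cell_ids)
        cells = self.cells[self.cells["cell_id"].isin(keep)].reset_index(drop=True)
        trials = self.trials[self.trials["cell_id"].isin(keep)].reset_index(drop=True)
        spikes = self.spikes[self.spikes["cell_id"].isin(keep)].reset_index(drop=True)
        return SpikeDataset(cells, trials, spikes)

    def spike_trains(self, cell_id) -> list[np.ndarray]:
        """Per-trial spike-time arrays for one cell, in trial order."""
        trials = self.trials[self.trials["cell_id"] == cell_id]
        grouped = dict(tuple(
            self.spikes[self.spikes["cell_id"] == cell_id]
            .groupby("trial_id")["spike_time_ms"]))
        return [grouped.get(tid, pd.Series(dtype=float)).to_numpy()
                for tid in trials["trial_id"]]

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(d / "cells.csv", index=False)
        self.trials.to_csv(d / "trials.csv", index=False)
        self.spikes.to_csv(d / "spikes.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SpikeDataset":
        d = Path(directory)
        return cls(cells=pd.read_csv(d / "cells.csv"),
                   trials=pd.read_csv(d / "trials.csv"),
                   spikes=pd.read_csv(d / "spikes.csv"))


def poisson_spikes(rate_hz: np.ndarray, time_ms: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a rate trajectory (Hz).

    Piecewise-constant intensity on the (uniform) time grid; spike counts
    per bin are Poisson with mean rate * bin / 1000 and times uniform
    within their bin.
    """
    rate_hz = np.maximum(np.asarray(rate_hz, dtype=float), 0.0)
    time_ms = np.asarray(time_ms, dtype=float)
    dt = time_ms[1] - time_ms[0] if len(time_ms) > 1 else 1.0
    counts = rng.poisson(rate_hz * dt / 1000.0)
    times = []
    for t0, c in zip(time_ms, counts):
        if c:
            times.append(t0 + rng.uniform(0.0, dt, size=c))
    return np.sort(np.concatenate(times)) if times else np.empty(0)


def generate_dataset(params: ModelParameters, n_cells: int = 6,
                     trials_per_block: int = 50, seed: int = 0,
                     set_sizes: Sequence[int] = (2, 4, 6),
                     options: EngineOptions = EngineOptions(),
                     subject: str = "synthetic") -> SpikeDataset:
    """Generate a synthetic spike/behavior dataset from the model.

    Each cell gets one session with one block per set size
    (``trials_per_block`` trials each).  RF locations rotate across cells
    so all six placeholder geometries occur.  Trial conditions are drawn
    uniformly over displayed positions and the two orientations; outcomes
    come from the model simulation, and spikes from the RF unit's simulated
    LIP rate trace over [-500, rt + 200] ms.
    """
    if n_cells < 1 or trials_per_block < 1:
        raise ValueError("n_cells and trials_per_block must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim_seeds = np.random.SeedSequence(seed + 1).spawn(n_cells)

    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "subject": subject,
        "session": np.arange(n_cells),
        "rf_location": [LIP_UNITS[i % 6] for i in range(n_cells)],
    })
    trial_rows = []
    spike_rows = []
    trial_id = 0
    for ci in range(n_cells):
        rf = cells.loc[ci, "rf_location"]
        rf_idx = LIP_UNITS.index(rf)
        cell_sim_seed = int(sim_seeds[ci].generate_state(1)[0] % (2 ** 31))
        for block, ss in enumerate(set_sizes):
            # uniform conditions; group identical conditions to batch them
            positions = rng.choice(_ACTIVE[ss], size=trials_per_block)
            orientations = rng.choice(["E_left", "E_right"],
                                      size=trials_per_block)
            conds = pd.DataFrame({"position": positions,
                                  "orientation": orientations})
            for (pos, ori), grp in conds.groupby(["position", "orientation"]):
                cond = TrialCondition(ss, pos, ori)
                batch = simulate_batch(
                    params, [cond], len(grp),
                    seed=cell_sim_seed + 13 * block + trial_id,
                    options=options, record_full=True)
                traces = batch.traces[cond]
                lip_hz = traces.lip_trials[:, rf_idx, :] * 1000.0
                for k, row in enumerate(batch.trials.itertuples()):
                    rt = row.rt_ms
                    t_end = (rt if np.isfinite(rt) else options.t_max) + 200.0
                    grid = traces.time_ms
                    sel = grid <= t_end
                    spikes = poisson_spikes(lip_hz[k][sel], grid[sel], rng)
                    trial_rows.append({
                        "trial_id": trial_id, "cell_id": ci, "session": ci,
                        "block": block, "set_size": ss, "position": pos,
                        "orientation": ori, "congruent": cond.congruent,
                        "response_side": row.response_side,
                        "correct": row.correct, "rt_ms": rt,
                        "timed_out": row.timed_out,
                    })
                    for t in spikes:
                        spike_rows.append({"cell_id": ci,
                                           "trial_id": trial_id,
                                           "spike_time_ms": float(t)})
                    trial_id += 1
    trials = pd.DataFrame(trial_rows)
    spikes = pd.DataFrame(spike_rows,
                          columns=["cell_id", "trial_id", "spike_time_ms"])
    return SpikeDataset(cells=cells, trials=trials, spikes=spikes)


def inject_artifacts(dataset: SpikeDataset,
                     n_hot_cells: int = 0, hot_rate_hz: float = 85.0,
                     n_missing_set_size_cells: int = 0,
                     missing_set_size: int = 6,
                     seed: int = 0) -> SpikeDataset:
    """Add pathological cells that the inclusion filters should remove.

    Hot cells fire as homogeneous Poisson at ``hot_rate_hz`` (above the
    80 Hz cutoff); missing-set-size cells copy an existing cell's trials
    but drop one set size.  With all counts zero the dataset is returned
    unchanged.
    """
    if n_hot_cells == 0 and n_missing_set_size_cells == 0:
        return dataset
    rng = np.random.default_rng(seed)
    cells = dataset.cells.copy()
    trials = dataset.trials.copy()
    spikes = dataset.spikes.copy()
    next_cell = int(cells["cell_id"].max()) + 1 if len(cells) else 0
    next_trial = int(trials["trial_id"].max()) + 1 if len(trials) else 0
    template = trials[trials["cell_id"] == cells["cell_id"].iloc[0]]

    def _add_cell(rf):
        nonlocal next_cell
        cid = next_cell
        next_cell += 1
        return cid, pd.DataFrame({
            "cell_id": [cid], "subject": ["artifact"],
            "session": [cid], "rf_location": [rf]})

    new_cells = []
    new_trials = []
    new_spikes = []
    for _ in range(n_hot_cells):
        cid, row = _add_cell("L1")
        new_cells.append(row)
        for _, trow in template.iterrows():
            t = trow.to_dict()
            t["trial_id"] = next_trial
            t["cell_id"] = cid
            t["session"] = cid
            new_trials.append(t)
            window = np.arange(-500.0,
                               (t["rt_ms"] if np.isfinite(t["rt_ms"])
                                else 1000.0) + 200.0)
            st = poisson_spikes(np.full(window.size, hot_rate_hz), window, rng)
            for s in st:
                new_spikes.append({"cell_id": cid, "trial_id": next_trial,
                                   "spike_time_ms": float(s)})
            next_trial += 1
    for _ in range(n_missing_set_size_cells):
        cid, row = _add_cell("R1")
        new_cells.append(row)
        kept = template[template["set_size"] != missing_set_size]
        for _, trow in kept.iterrows():
            t = trow.to_dict()
            t["trial_id"] = next_trial
            t["cell_id"] = cid
            t["session"] = cid
            new_trials.append(t)
            next_trial += 1
    cells = pd.concat([cells] + new_cells, ignore_index=True)
    if new_trials:
        trials = pd.concat([trials, pd.DataFrame(new_trials)],
                           ignore_index=True)
    if new_spikes:
        spikes = pd.concat([spikes, pd.DataFrame(new_spikes)],
                           ignore_index=True)
    return SpikeDataset(cells=cells, trials=trials, spikes=spikes)
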