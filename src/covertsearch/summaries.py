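"""Behavioral and neural summary statistics for the covert-search task.

Covers the analysis conventions used throughout the package: reaction-time
quantile bins, accuracy-versus-RT profiles in 100-ms bins, the congruence
split, the decision-time decomposition, Gaussian-kernel firing-rate
estimation from spike trains, the mapping from model LIP units to
target/distractor condition labels, and the cell-inclusion filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import LIP_UNITS, ModelParameters, TrialCondition
from .sde_engine import BatchResult, ConditionTraces

__all__ = [
    "FRTrace",
    "AccuracyRtBins",
    "TARGET_IN_RF",
    "DISTRACTOR_SAME",
    "DISTRACTOR_OPPOSITE",
    "classify_congruence",
    "decision_time",
    "rt_quantile_bins",
    "fr_from_spikes",
    "unit_condition_labels",
    "model_fr_traces",
    "accuracy_vs_rt",
    "filter_cells",
]

QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)

# condition labels for LIP firing-rate comparisons
TARGET_IN_RF = "target_in_rf"
DISTRACTOR_SAME = "distractor_same_hemifield"
DISTRACTOR_OPPOSITE = "distractor_opposite_hemifield"


@dataclass
class FRTrace:
    """A firing-rate trace (Hz) on a uniform time grid aligned to cue onset."""

    time_ms: np.ndarray
    rate_hz: np.ndarray
    sem_hz: Optional[np.ndarray] = None
    label: Optional[str] = None
    n_trials: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        if len(t) > 1 and not np.allclose(np.diff(t), t[1] - t[0]):
            raise ValueError("time grid must be uniform")


@dataclass
class AccuracyRtBins:
    """Per-bin accuracy in 100-ms RT bins, keyed by (set size, congruence).

    ``table`` columns: set_size, congruent, bin_left_ms, bin_right_ms,
    n_trials, n_correct, accuracy.  Bins with no trials are omitted rather
    than reported as 0%.
    """

    bin_width_ms: float
    table: pd.DataFrame


def classify_congruence(condition: TrialCondition) -> str:
    """"congruent" when the correct release side matches the target hemifield."""
    return "congruent" if condition.congruent else "incongruent"


def decision_time(mean_rt: float, params: ModelParameters) -> float:
    """Mean RT minus the sensory, search and motor latencies (ms).

    Subtracts p_delay + t_delay + t_0 from a mean RT, attributing the
    remainder to the accumulation (decision) process.
    """
    return float(mean_rt) - params.delay_sum


def rt_quantile_bins(rt_samples: Iterable[float]) -> np.ndarray:
    """Five bin edges at the 0.1/0.3/0.5/0.7/0.9 RT quantiles.

    The edges define six bins whose outer two hold 10% of the sample mass
    each and inner four hold 20% each (linear order-statistic
    interpolation).  Requires a non-empty sample; with fewer than 5 samples
    the edges degenerate but remain ordered.
    """
    rts = np.asarray(list(rt_samples), dtype=float)
    if rts.size == 0:
        raise ValueError("rt_quantile_bins: empty sample")
    return np.quantile(rts, QUANTILES)


def bin_counts(samples: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts of samples in the six bins defined by the five quantile edges."""
    return np.bincount(np.searchsorted(edges, np.asarray(samples, float),
                                       side="left"),
                       minlength=len(edges) + 1).astype(float)


def fr_from_spikes(spike_times_per_trial: Sequence[np.ndarray],
                   sigma_ms: float = 15.0,
                   grid_ms: Optional[np.ndarray] = None,
                   label: Optional[str] = None) -> FRTrace:
    """Trial-averaged firing rate by Gaussian-kernel smoothing (sigma 15 ms).

    Each spike contributes a unit-area Gaussian (area measured in seconds,
    so rates come out in Hz) evaluated on the grid; traces are averaged
    across trials and the SEM taken over trials.  No boundary correction is
    applied at the window edges.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be > 0")
    if grid_ms is None:
        grid_ms = np.arange(-200.0, 801.0)
    grid_ms = np.asarray(grid_ms, dtype=float)
    n_trials = len(spike_times_per_trial)
    traces = np.zeros((max(n_trials, 1), len(grid_ms)))
    norm = 1000.0 / (np.sqrt(2.0 * np.pi) * sigma_ms)  # unit area in seconds
    for i, spikes in enumerate(spike_times_per_trial):
        spikes = np.asarray(spikes, dtype=float)
        if spikes.size == 0:
            continue
        d = (grid_ms[None, :] - spikes[:, None]) / sigma_ms
        traces[i] = norm * np.exp(-0.5 * d ** 2).sum(axis=0)
    mean = traces[:n_trials].mean(axis=0) if n_trials else traces[0]
    sem = (traces[:n_trials].std(axis=0, ddof=1) / np.sqrt(n_trials)
           if n_trials > 1 else np.zeros_like(mean))
    return FRTrace(time_ms=grid_ms, rate_hz=mean, sem_hz=sem, label=label,
                   n_trials=n_trials)


def unit_condition_labels(condition: TrialCondition) -> dict[str, str]:
    """Map each stimulated LIP unit to its condition label for one trial.

    The unit whose RF holds the target is ``target_in_rf``; other
    stimulated units are distractors in the same or opposite hemifield as
    the target.  Units without stimulus input at this set size are omitted
    (their FRs are excluded from comparisons).  At set size 2 the two
    stimuli necessarily lie in opposite hemifields, so no same-hemifield
    distractor label exists.
    """
    active = {2: ("L1", "R1"), 4: ("L1", "R1", "L2", "R2"),
              6: LIP_UNITS}[condition.set_size]
    labels = {}
    for unit in active:
        if unit == condition.position:
            labels[unit] = TARGET_IN_RF
        elif unit[0] == condition.target_hemifield:
            labels[unit] = DISTRACTOR_SAME
        else:
            labels[unit] = DISTRACTOR_OPPOSITE
    return labels


def model_fr_traces(batch: BatchResult,
                    condition: TrialCondition) -> dict[str, FRTrace]:
    """Per-unit mean LIP firing rates (Hz) labeled by trial role.

    Requires the batch to have been run with ``record_trajectories``.
    Returns one FRTrace per stimulated unit, keyed by unit name, with
    ``label`` set per :func:`unit_condition_labels`.
    """
    if condition not in batch.traces:
        raise ValueError(f"batch has no recorded trajectories for {condition}")
    tr: ConditionTraces = batch.traces[condition]
    lip_hz = tr.lip_mean_hz()
    n = int((batch.trials[["set_size", "position", "orientation"]]
             .eq([condition.set_size, condition.position,
                  condition.orientation]).all(axis=1)).sum())
    labels = unit_condition_labels(condition)
    out = {}
    for i, unit in enumerate(LIP_UNITS):
        if unit not in labels:
            continue
        out[unit] = FRTrace(time_ms=tr.time_ms, rate_hz=lip_hz[i],
                            sem_hz=tr.sem[i] * 1000.0, label=labels[unit],
                            n_trials=n)
    return out


def label_averaged_traces(batch: BatchResult,
                          condition: TrialCondition) -> dict[str, FRTrace]:
    """Mean LIP firing rate per condition label (units sharing a label
    averaged), e.g. the single 'distractor in RF opposite target' trace."""
    per_unit = model_fr_traces(batch, condition)
    out: dict[str, FRTrace] = {}
    by_label: dict[str, list[FRTrace]] = {}
    for trace in per_unit.values():
        by_label.setdefault(trace.label, []).append(trace)
    for lab, traces in by_label.items():
        rate = np.mean([t.rate_hz for t in traces], axis=0)
        out[lab] = FRTrace(time_ms=traces[0].time_ms, rate_hz=rate,
                           label=lab, n_trials=traces[0].n_trials)
    return out


def accuracy_vs_rt(trials: pd.DataFrame,
                   bin_width_ms: float = 100.0) -> AccuracyRtBins:
    """Accuracy in fixed-width RT bins, split by set size and congruence.

    Timeouts are excluded; empty bins are omitted.  Counts across occupied
    bins sum to the number of completed trials.
    """
    if len(trials) == 0:
        raise ValueError("accuracy_vs_rt: no trials")
    done = trials[~trials["timed_out"]].copy()
    done["bin_left_ms"] = (done["rt_ms"] // bin_width_ms) * bin_width_ms
    rows = []
    for (ss, cong, left), grp in done.groupby(
            ["set_size", "congruent", "bin_left_ms"]):
        rows.append({
            "set_size": ss, "congruent": cong,
            "bin_left_ms": left, "bin_right_ms": left + bin_width_ms,
            "n_trials": len(grp), "n_correct": int(grp["correct"].sum()),
            "accuracy": float(grp["correct"].mean()),
        })
    return AccuracyRtBins(bin_width_ms=bin_width_ms,
                          table=pd.DataFrame(rows))


def filter_cells(dataset, max_fr_hz: float = 80.0,
                 required_set_sizes: Sequence[int] = (2, 4, 6),
                 sigma_ms: float = 15.0):
    """Apply the cell-inclusion rules to a spike dataset.

    Removes cells whose maximum smoothed firing rate (Gaussian kernel,
    ``sigma_ms``) exceeds ``max_fr_hz``, and cells lacking trials at any of
    the required set sizes.  Returns a new dataset of the same type.
    """
    keep = []
    for cell_id in dataset.cells["cell_id"]:
        cell_trials = dataset.trials[dataset.trials["cell_id"] == cell_id]
        sizes = set(cell_trials["set_size"].unique())
        if not set(required_set_sizes) <= sizes:
            continue
        spikes = [
            dataset.spikes.loc[
                (dataset.spikes["cell_id"] == cell_id)
                & (dataset.spikes["trial_id"] == tid),
                "spike_time_ms"].to_numpy()
            for tid in cell_trials["trial_id"]
        ]
        if spikes:
            lo = min((s.min() for s in spikes if s.size), default=0.0)
            hi = max((s.max() for s in spikes if s.size), default=1.0)
            grid = np.arange(lo - 50.0, hi + 51.0)
            trace = fr_from_spikes(spikes, sigma_ms=sigma_ms, grid_ms=grid)
            if trace.rate_hz.max() > max_fr_hz:
                continue
        keep.append(cell_id)
    return dataset.subset(keep)
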