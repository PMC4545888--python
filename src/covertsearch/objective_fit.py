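"""Joint neural/behavioral objective and parameter fitting.

The objective combines (i) a relative squared error between simulated and
reference LIP firing-rate traces over [0, 800] ms from cue onset and (ii)
quantile chi-square statistics comparing reaction-time distributions,
computed separately for correct and error trials and for the congruent and
incongruent hemifield conditions:

    alpha_FR * FRterm
      + alpha_corr  * (1/2) * sum_{cong,incong} chi2_correct
      + alpha_incorr * (1/2) * sum_{cong,incong} chi2_error

with default weights alpha_corr = alpha_incorr = 1 and alpha_FR = 0.25.
The chi-square follows the RT-quantile method: the reference RTs define six
bins at their 0.1/0.3/0.5/0.7/0.9 quantiles, model RTs are binned into the
same edges, model counts are rescaled to the reference sample size, and
chi2 = sum (data_n - model_n)^2 / model_n.

Fitting runs a simulated-annealing stage followed by bounded Nelder-Mead
refinement, with common random numbers (a fixed simulation seed across
objective calls) so the objective surface is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .model_core import (
    PER_SUBJECT_NAMES,
    SHARED_NAMES,
    ModelParameters,
    TrialCondition,
)
from .sde_engine import BatchResult, EngineOptions, simulate_batch
from .summaries import (
    DISTRACTOR_OPPOSITE,
    DISTRACTOR_SAME,
    TARGET_IN_RF,
    label_averaged_traces,
    bin_counts,
    rt_quantile_bins,
)

__all__ = [
    "ObjectiveConfig",
    "ObjectiveValue",
    "DataBundle",
    "ParameterVector",
    "chi_square_rt",
    "fr_error_term",
    "bundle_from_batches",
    "simulate_reference_bundle",
    "objective",
    "joint_objective",
    "fit",
    "fit_model",
]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights, windows and simulation sizes for the composite objective."""

    alpha_fr: float = 0.25
    alpha_corr: float = 1.0
    alpha_incorr: float = 1.0
    fr_window_ms: tuple[float, float] = (0.0, 800.0)
    fr_step_ms: float = 1.0
    eps_fr_hz: float = 1.0       # floor on reference FRs in the denominator
    eps_count: float = 1.0       # floor on expected model bin counts
    n_sim: int = 6000
    min_class_trials: int = 12   # sparse correct/error classes skip chi2
    set_size: int = 4
    engine: EngineOptions = field(default_factory=EngineOptions)

    def __post_init__(self) -> None:
        if min(self.alpha_fr, self.alpha_corr, self.alpha_incorr) < 0:
            raise ValueError("objective weights must be >= 0")
        if self.fr_window_ms[1] > self.engine.traj_t_max:
            raise ValueError("FR window must lie within the recorded range")


@dataclass
class ObjectiveValue:
    """Breakdown of one objective evaluation."""

    fr_term: float
    chi2_correct: dict[str, float]   # per congruence condition
    chi2_error: dict[str, float]
    total: float
    n_timeouts: int = 0


# Conditions used for fitting: a right-facing target at upper right
# (congruent) or upper left (incongruent); parameters are mirror-symmetric,
# so these two configurations cover both hemifield cases.
def fitting_conditions(set_size: int = 4) -> dict[str, TrialCondition]:
    return {
        "congruent": TrialCondition(set_size, "R1", "E_right"),
        "incongruent": TrialCondition(set_size, "L1", "E_right"),
    }


@dataclass
class DataBundle:
    """Reference data for the objective, per congruence condition.

    ``fr``: {condition: {label: rate array (Hz) on the FR grid}} with labels
    from :mod:`covertsearch.summaries`;
    ``rt_correct`` / ``rt_error``: {condition: RT samples (ms)}.
    """

    time_ms: np.ndarray
    fr: dict[str, dict[str, np.ndarray]]
    rt_correct: dict[str, np.ndarray]
    rt_error: dict[str, np.ndarray]
    set_size: int = 4


def chi_square_rt(data_rts: np.ndarray, model_rts: np.ndarray,
                  eps_count: float = 1.0) -> float:
    """Quantile chi-square between a reference and a model RT sample.

    Bins come from the reference sample's 0.1/0.3/0.5/0.7/0.9 quantiles;
    model counts are rescaled to expected counts (model proportion times
    reference N) and floored at ``eps_count``.  An empty model sample
    returns a large penalty (all reference mass against the floor).
    """
    data_rts = np.asarray(data_rts, dtype=float)
    model_rts = np.asarray(model_rts, dtype=float)
    if data_rts.size == 0:
        raise ValueError("chi_square_rt: empty reference sample")
    edges = rt_quantile_bins(data_rts)
    n_data = bin_counts(data_rts, edges)
    if model_rts.size == 0:
        expected = np.full(6, eps_count)
    else:
        expected = bin_counts(model_rts, edges) / model_rts.size * data_rts.size
        expected = np.maximum(expected, eps_count)
    return float(np.sum((n_data - expected) ** 2 / expected))


def fr_error_term(model_fr: dict[str, dict[str, np.ndarray]],
                  data_fr: dict[str, dict[str, np.ndarray]],
                  set_size: int, eps_fr_hz: float = 1.0) -> float:
    """Relative squared FR error, averaged as 1/(2*SS) over conditions/units.

    ``model_fr`` and ``data_fr`` map condition -> label -> trace (Hz) on a
    shared grid.  Each stimulated unit contributes one squared-relative
    -error sum over the grid against the reference trace for its label;
    reference values are floored at ``eps_fr_hz`` in the denominator.
    """
    total = 0.0
    for cond, model_labels in model_fr.items():
        data_labels = data_fr[cond]
        for lab, m in model_labels.items():
            d = data_labels[lab]
            if m.shape != d.shape:
                raise ValueError("FR grids do not match")
            denom = np.maximum(d, eps_fr_hz)
            # weight by the number of units carrying this label so every
            # stimulated unit contributes one term
            total += _label_multiplicity(lab, set_size) * float(
                np.sum(((m - d) / denom) ** 2))
    return total / (2.0 * set_size)


def _label_multiplicity(label: str, set_size: int) -> int:
    if label == TARGET_IN_RF:
        return 1
    if label == DISTRACTOR_SAME:
        return {2: 0, 4: 1, 6: 2}[set_size]
    if label == DISTRACTOR_OPPOSITE:
        return {2: 1, 4: 2, 6: 3}[set_size]
    raise KeyError(label)


def _fr_grid_slice(time_ms: np.ndarray, window: tuple[float, float]) -> slice:
    i0 = int(np.searchsorted(time_ms, window[0]))
    i1 = int(np.searchsorted(time_ms, window[1], side="right"))
    return slice(i0, i1)


def _batch_label_fr(batch: BatchResult, condition: TrialCondition,
                    sl: slice) -> dict[str, np.ndarray]:
    return {lab: tr.rate_hz[sl]
            for lab, tr in label_averaged_traces(batch, condition).items()}


def bundle_from_batches(batches: dict[str, BatchResult],
                        config: ObjectiveConfig = ObjectiveConfig()) -> DataBundle:
    """Build a reference bundle from simulated batches keyed by congruence."""
    conds = fitting_conditions(config.set_size)
    first = next(iter(batches.values()))
    time_full = first.traces[next(iter(first.traces))].time_ms
    sl = _fr_grid_slice(time_full, config.fr_window_ms)
    fr = {}
    rt_c = {}
    rt_e = {}
    for name, cond in conds.items():
        batch = batches[name]
        fr[name] = _batch_label_fr(batch, cond, sl)
        rt_c[name] = batch.rts(correct=True)
        rt_e[name] = batch.rts(correct=False)
    return DataBundle(time_ms=time_full[sl], fr=fr, rt_correct=rt_c,
                      rt_error=rt_e, set_size=config.set_size)


def _simulate_fitting_batches(params: ModelParameters, config: ObjectiveConfig,
                              seed: int) -> dict[str, BatchResult]:
    out = {}
    ss = np.random.SeedSequence(seed).spawn(2)
    for (name, cond), child in zip(fitting_conditions(config.set_size).items(),
                                   ss):
        out[name] = simulate_batch(
            params, [cond], config.n_sim,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
            options=config.engine, record_trajectories=True)
    return out


def simulate_reference_bundle(params: ModelParameters,
                              config: ObjectiveConfig,
                              seed: int) -> DataBundle:
    """Simulate the model and package the results as a reference bundle
    (used for self-fit checks and parameter-recovery experiments)."""
    return bundle_from_batches(_simulate_fitting_batches(params, config, seed),
                               config)


def objective(params: ModelParameters, bundle: DataBundle,
              config: ObjectiveConfig = ObjectiveConfig(),
              seed: int = 0) -> ObjectiveValue:
    """Evaluate the composite objective for one subject."""
    batches = _simulate_fitting_batches(params, config, seed)
    conds = fitting_conditions(config.set_size)
    sl = _fr_grid_slice(batches["congruent"].traces[
        conds["congruent"]].time_ms, config.fr_window_ms)
    model_fr = {name: _batch_label_fr(batches[name], cond, sl)
                for name, cond in conds.items()}
    fr_term = fr_error_term(model_fr, bundle.fr, bundle.set_size,
                            config.eps_fr_hz)
    chi_c = {}
    chi_e = {}
    for name in conds:
        batch = batches[name]
        if bundle.rt_correct[name].size >= config.min_class_trials:
            chi_c[name] = chi_square_rt(bundle.rt_correct[name],
                                        batch.rts(correct=True),
                                        config.eps_count)
        else:
            chi_c[name] = 0.0
        if bundle.rt_error[name].size >= config.min_class_trials:
            chi_e[name] = chi_square_rt(bundle.rt_error[name],
                                        batch.rts(correct=False),
                                        config.eps_count)
        else:
            chi_e[name] = 0.0
    total = (config.alpha_fr * fr_term
             + config.alpha_corr * 0.5 * sum(chi_c.values())
             + config.alpha_incorr * 0.5 * sum(chi_e.values()))
    n_to = sum(b.n_timeouts for b in batches.values())
    return ObjectiveValue(fr_term=fr_term, chi2_correct=chi_c,
                          chi2_error=chi_e, total=total, n_timeouts=n_to)


def joint_objective(params_pair: dict[str, ModelParameters],
                    bundles: dict[str, DataBundle],
                    config: ObjectiveConfig = ObjectiveConfig(),
                    seed: int = 0) -> float:
    """Sum of per-subject objectives for a joint two-subject fit."""
    total = 0.0
    for i, (subject, params) in enumerate(sorted(params_pair.items())):
        total += objective(params, bundles[subject], config,
                           seed=seed + i).total
    return total


# ---------------------------------------------------------------------------
# Parameter packing: 18 shared + 13 per subject x 2 = 44 free values
# ---------------------------------------------------------------------------


@dataclass
class ParameterVector:
    """Pack/unpack the joint free-parameter vector across two subjects.

    Layout: the 18 shared values first, then the 13 subject-specific values
    for each subject in ``subjects`` order.
    """

    subjects: tuple[str, str] = ("m11", "m12")

    @property
    def n_free(self) -> int:
        return len(SHARED_NAMES) + len(PER_SUBJECT_NAMES) * len(self.subjects)

    @property
    def names(self) -> list[str]:
        out = [f"shared:{n}" for n in SHARED_NAMES]
        for s in self.subjects:
            out += [f"{s}:{n}" for n in PER_SUBJECT_NAMES]
        return out

    def pack(self, params: dict[str, ModelParameters]) -> np.ndarray:
        first = params[self.subjects[0]]
        for name in SHARED_NAMES:
            vals = {getattr(params[s], name) for s in self.subjects}
            if len(vals) != 1:
                raise ValueError(f"shared parameter {name} differs between "
                                 f"subjects")
        vec = [getattr(first, name) for name in SHARED_NAMES]
        for s in self.subjects:
            vec += [getattr(params[s], name) for name in PER_SUBJECT_NAMES]
        return np.array(vec)

    def unpack(self, vec: np.ndarray) -> dict[str, ModelParameters]:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_free,):
            raise ValueError(f"expected a vector of length {self.n_free}")
        shared = dict(zip(SHARED_NAMES, vec[:len(SHARED_NAMES)]))
        out = {}
        off = len(SHARED_NAMES)
        for s in self.subjects:
            own = dict(zip(PER_SUBJECT_NAMES,
                           vec[off:off + len(PER_SUBJECT_NAMES)]))
            off += len(PER_SUBJECT_NAMES)
            out[s] = ModelParameters(**shared, **own)
        return out


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    x: np.ndarray
    fun: float
    trace: list[tuple[int, float]]    # (eval index, objective) improvements
    n_evals: int
    budget_exhausted: bool
    params: Optional[ModelParameters] = None


def fit(objective_fn: Callable[[np.ndarray], float], x0: np.ndarray,
        bounds: Sequence[tuple[float, float]], seed: int = 0,
        sa_iters: int = 0, nm_maxfev: int = 200,
        budget: Optional[int] = None,
        simplex_step: float = 0.45) -> FitResult:
    """Minimize a (possibly noisy) objective over a box.

    A simulated-annealing stage (``sa_iters`` > 0) explores globally, then
    bounded Nelder-Mead refines the best point.  The Nelder-Mead stage works
    in coordinates scaled by the starting point and opens with a large
    initial simplex (``simplex_step`` as a fraction of each scaled
    coordinate, alternating sign): simulation-based objectives of this kind
    are locally jagged (quantile bin counts change discretely), and a wide
    simplex steps over those barriers where the default small one stalls.
    ``budget`` caps total function evaluations; the best-so-far point is
    returned with ``budget_exhausted`` set if the cap was hit.
    Deterministic for a fixed seed when ``objective_fn`` is.
    """
    x0 = np.asarray(x0, dtype=float)
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for xi, (lo, hi) in zip(x0, bounds):
        if not (lo <= xi <= hi):
            raise ValueError("x0 must lie within bounds")
    state = {"n": 0, "best": np.inf, "bestx": x0.copy(), "trace": [],
             "stop": False}

    class _Budget(Exception):
        pass

    def wrapped(x):
        if budget is not None and state["n"] >= budget:
            raise _Budget()
        state["n"] += 1
        val = float(objective_fn(np.asarray(x, dtype=float)))
        if val < state["best"]:
            state["best"] = val
            state["bestx"] = np.asarray(x, dtype=float).copy()
            state["trace"].append((state["n"], val))
        return val

    exhausted = False
    try:
        x_start = x0
        if sa_iters > 0:
            res = optimize.dual_annealing(
                wrapped, bounds=bounds, x0=x0, maxiter=sa_iters,
                seed=seed, no_local_search=True)
            x_start = np.clip(res.x, [b[0] for b in bounds],
                              [b[1] for b in bounds])
        if nm_maxfev > 0:
            # optimize in coordinates scaled by the starting point so the
            # simplex treats parameters of different magnitudes evenly
            scale = np.where(np.abs(x_start) > 1e-12, np.abs(x_start), 1.0)
            sbounds = [(lo / s, hi / s) for (lo, hi), s in zip(bounds, scale)]
            z0 = x_start / scale
            n_dim = len(z0)
            sim = np.vstack([z0] + [
                np.clip(z0 + ((-1) ** (i + 1)) * simplex_step * np.eye(n_dim)[i],
                        [b[0] for b in sbounds], [b[1] for b in sbounds])
                for i in range(n_dim)])
            optimize.minimize(lambda z: wrapped(z * scale), z0,
                              method="Nelder-Mead", bounds=sbounds,
                              options={"maxfev": nm_maxfev, "xatol": 1e-4,
                                       "fatol": 1e-6, "adaptive": True,
                                       "initial_simplex": sim})
    except _Budget:
        exhausted = True
    return FitResult(x=state["bestx"], fun=state["best"],
                     trace=state["trace"], n_evals=state["n"],
                     budget_exhausted=exhausted)


def fit_model(bundle: DataBundle, base_params: ModelParameters,
              free_names: Sequence[str],
              bounds: dict[str, tuple[float, float]],
              config: ObjectiveConfig = ObjectiveConfig(),
              seed: int = 0, sa_iters: int = 0, nm_maxfev: int = 200,
              budget: Optional[int] = None) -> FitResult:
    """Fit a subset of one subject's parameters to a reference bundle.

    ``free_names`` are ModelParameters field names; all other parameters
    stay clamped at ``base_params``.  The simulation seed is held fixed
    across objective calls (common random numbers), which makes the
    objective deterministic and, for a bundle generated with the same seed,
    places its minimum at the generating parameters.
    """
    free_names = list(free_names)
    x0 = np.array([getattr(base_params, n) for n in free_names])
    bnds = [bounds[n] for n in free_names]

    def fn(x: np.ndarray) -> float:
        params = base_params.replace(**dict(zip(free_names, x)))
        return objective(params, bundle, config, seed=seed).total

    result = fit(fn, x0, bnds, seed=seed, sa_iters=sa_iters,
                 nm_maxfev=nm_maxfev, budget=budget)
    result.params = base_params.replace(**dict(zip(free_names, result.x)))
    return result
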