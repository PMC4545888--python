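"""Stochastic integration of the 20-SDE covert-search model.

Trials integrate from cue onset (t = 0) with a stochastic Heun (second-order
Runge-Kutta for additive noise) scheme at dt = 0.5 ms by default.  A trial
ends when one motor unit crosses the response threshold ``theta`` (the
reported RT adds the nondecision time ``T_0``) or at ``t_max`` (timeout).

The hot loop is a numba kernel with one independent RNG stream per trial;
per-trial seeds are derived from the master seed, so batches are bit-exact
reproducible.  When trajectories are recorded, integration continues past
the threshold crossing to ``t_max`` so that post-response dynamics (the
motor-feedback suppression of LIP and IT) appear in the averaged traces.

:func:`covertsearch.model_core.drift` is the pure-numpy reference for the
same equations; the two implementations are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .model_core import (
    FIXED,
    LipTopology,
    ModelParameters,
    TrialCondition,
    condition_inputs,
)

__all__ = [
    "EngineOptions",
    "TrialResult",
    "ConditionTraces",
    "BatchResult",
    "simulate_trial",
    "simulate_batch",
]

# parameter-vector layout handed to the numba kernel
_P_ORDER = (
    "p_delay", "t_delay", "tau_m", "tau_it", "tau_aip", "tau_lip",
    "eta_maipit", "eta_lip", "eta_lip_decay1", "eta_lip_decay2",
    "alpha_lip", "w_aipm", "w_itaip", "w_lipaip", "w_aiplip",
    "beta_aiplip", "beta_maip", "beta_mitlip", "s_lip", "s_tar",
    "s_back", "s_ori", "c_maip", "c_it", "c_lip", "k_m", "g_m",
    "k_aip", "g_aip", "t_0", "theta",
)
# fixed constants appended after the 31 fitted values
_IP_TAU_LIP_NOISE = 31
_IP_TAU_IT_NOISE = 32
_IP_CAP = 33

@dataclass(frozen=True)
class EngineOptions:
    """Numerical options for the SDE integrator.

    dt and t_max in ms.  ``scheme`` is "rk2" (stochastic Heun, default) or
    "euler".  ``lip_leak`` toggles the -X leak in the LIP rate equations;
    ``noise_scaling`` selects the amplitude convention for an equation
    written tau dX = f dt + c xi(t): "tau" -> c/tau (literal), "sqrt_tau"
    -> c/sqrt(tau).  ``clamp_nonneg`` keeps the gated accumulators (AIP,
    motor) non-negative.  Trajectories are sampled every ``traj_sample_ms``.
    """

    dt: float = FIXED.dt
    t_max: float = 1500.0
    scheme: str = "rk2"
    lip_leak: bool = True
    noise_scaling: str = "tau"
    clamp_nonneg: bool = True
    traj_sample_ms: float = 1.0
    traj_t_max: float = 800.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be > 0")
        if self.scheme not in ("rk2", "euler"):
            raise ValueError("scheme must be 'rk2' or 'euler'")
        if self.noise_scaling not in ("tau", "sqrt_tau"):
            raise ValueError("noise_scaling must be 'tau' or 'sqrt_tau'")
        ratio = self.traj_sample_ms / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("traj_sample_ms must be a multiple of dt")
        if self.traj_t_max > self.t_max:
            raise ValueError("traj_t_max must not exceed t_max")


@dataclass
class TrialResult:
    """Outcome of a single simulated trial."""

    response_side: str  # "L", "R", or "none"
    correct: bool
    rt_ms: float  # crossing time + T_0 (nan on timeout)
    crossing_time_ms: float  # nan on timeout
    timed_out: bool
    seed: int
    condition: TrialCondition
    trajectory_t: Optional[np.ndarray] = None  # ms
    trajectory: Optional[np.ndarray] = None  # (T, 20) state samples


@dataclass
class ConditionTraces:
    """Mean and SEM state trajectories for one condition (units: kHz)."""

    condition: TrialCondition
    time_ms: np.ndarray  # (T,)
    mean: np.ndarray  # (20, T)
    sem: np.ndarray  # (20, T)
    lip_trials: Optional[np.ndarray] = None  # (n, 6, T) per-trial LIP traces

    def lip_mean_hz(self) -> np.ndarray:
        """(6, T) mean LIP firing rates in Hz, rows ordered as LIP_UNITS."""
        return self.mean[0:6] * 1000.0


@dataclass
class BatchResult:
    """Trials and (optionally) averaged trajectories from a batch run.

    ``trials`` columns: set_size, position, orientation, congruent,
    response_side, correct, rt_ms, crossing_time_ms, timed_out, seed.
    Accuracy excludes timeouts.
    """

    trials: pd.DataFrame
    traces: dict[TrialCondition, ConditionTraces] = field(default_factory=dict)

    @property
    def n_timeouts(self) -> int:
        return int(self.trials["timed_out"].sum())

    def completed(self) -> pd.DataFrame:
        return self.trials[~self.trials["timed_out"]]

    def accuracy(self, congruent: Optional[bool] = None) -> float:
        done = self.completed()
        if congruent is not None:
            done = done[done["congruent"] == congruent]
        if len(done) == 0:
            return float("nan")
        return float(done["correct"].mean())

    def mean_rt(self, congruent: Optional[bool] = None,
                correct: Optional[bool] = None) -> float:
        rts = self.rts(congruent=congruent, correct=correct)
        return float(rts.mean()) if len(rts) else float("nan")

    def sem_rt(self, congruent: Optional[bool] = None,
               correct: Optional[bool] = None) -> float:
        rts = self.rts(congruent=congruent, correct=correct)
        return float(rts.std(ddof=1) / math.sqrt(len(rts))) if len(rts) > 1 \
            else float("nan")

    def rts(self, congruent: Optional[bool] = None,
            correct: Optional[bool] = None) -> np.ndarray:
        done = self.completed()
        if congruent is not None:
            done = done[done["congruent"] == congruent]
        if correct is not None:
            done = done[done["correct"] == correct]
        return done["rt_ms"].to_numpy()


def _params_vector(params: ModelParameters) -> np.ndarray:
    p = np.empty(34)
    for i, name in enumerate(_P_ORDER):
        p[i] = getattr(params, name)
    p[_IP_TAU_LIP_NOISE] = FIXED.tau_lip_noise
    p[_IP_TAU_IT_NOISE] = FIXED.tau_it_noise
    p[_IP_CAP] = FIXED.motor_cap
    return p


def _noise_amplitudes(params: ModelParameters, noise_scaling: str) -> np.ndarray:
    if noise_scaling == "tau":
        d = lambda tau: tau
    else:
        d = lambda tau: math.sqrt(tau)
    sig = np.empty(12)
    sig[0:6] = params.c_lip / d(FIXED.tau_lip_noise)
    sig[6:8] = params.c_it / d(FIXED.tau_it_noise)
    sig[8:10] = params.c_maip / d(params.tau_aip)
    sig[10:12] = params.c_maip / d(params.tau_m)
    return sig


@njit(cache=True, fastmath=True)
def _phi_nb(I: float) -> float:
    u = I - 0.384
    z = 352.0 * u
    # outside |z| <= 36 the exponential term is negligible (|error| < 1e-15)
    if z < -36.0:
        return 0.001
    if z > 36.0:
        return 0.001 + 0.352 * u / (1.0 + 3.52 * u)
    if abs(z) < 1e-12:
        return 0.001 + 0.352 / (352.0 + 3.52)
    return 0.001 + 0.352 * u / (-math.expm1(-z) + 3.52 * u)


@njit(cache=True, fastmath=True)
def _drift_nb(x, t, p, W, i_per, i_tar, i_ori, lip_leak, f):
    imi = p[17] * (x[18] + x[19])
    imaip = p[16] * (x[18] + x[19])
    on_per = 1.0 if t >= p[0] else 0.0
    on_tar = 1.0 if t >= p[0] + p[1] else 0.0
    for j in range(6):
        inh = 0.0
        for k in range(6):
            inh += W[j, k] * x[k]
        if j < 3:
            aip = p[14] * x[16] - p[15] * x[17]
        else:
            aip = p[14] * x[17] - p[15] * x[16]
        arg = aip + p[10] * x[j] - imi - inh + x[6 + j]
        r = _phi_nb(arg)
        if lip_leak:
            r -= x[j]
        f[j] = r / p[5]
        f[6 + j] = (-x[6 + j] + i_per[j] * on_per + i_tar[j] * on_tar
                    + p[20]) / p[31]
    for j in range(2):
        o = 1 - j
        f[12 + j] = (_phi_nb(x[14 + j] - p[6] * x[12 + o] - imi)
                     - x[12 + j]) / p[3]
        f[14 + j] = (-x[14 + j] + i_ori[j] * on_tar) / p[32]
    lip_l = x[0] + x[1] + x[2]
    lip_r = x[3] + x[4] + x[5]
    for j in range(2):
        o = 1 - j
        lips = lip_l if j == 0 else lip_r
        gin = p[12] * x[12 + j] + p[13] * lips - imaip - p[28]
        if gin < 0.0:
            gin = 0.0
        f[16 + j] = (-p[27] * x[16 + j] - p[6] * x[16 + o] + gin) / p[4]
        gm = p[11] * x[16 + j] - p[26]
        if gm < 0.0:
            gm = 0.0
        f[18 + j] = (-p[25] * x[18 + j] - p[6] * x[18 + o] + gm) / p[2]


@njit(cache=True, fastmath=True)
def _run_trials(p, W, sig, i_per, i_tar, i_ori, seeds, n_steps, dt,
                rk2, lip_leak, clamp, record_mode, rec_every, rec_steps,
                crossing, side, traj_sum, traj_sqsum, lip_full):
    n = seeds.shape[0]
    sqdt = math.sqrt(dt)
    theta = p[30]
    cap = p[33]
    x = np.zeros(20)
    xp = np.zeros(20)
    f1 = np.zeros(20)
    f2 = np.zeros(20)
    psi = np.zeros(12)
    noise_idx = np.array([6, 7, 8, 9, 10, 11, 14, 15, 16, 17, 18, 19],
                         dtype=np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        for j in range(20):
            x[j] = 0.0
        crossing[i] = -1.0
        side[i] = -1
        if record_mode >= 1:
            for j in range(20):
                traj_sum[j, 0] += x[j]
                traj_sqsum[j, 0] += x[j] * x[j]
        if record_mode == 2:
            for j in range(6):
                lip_full[i, j, 0] = x[j]
        for k in range(n_steps):
            t = k * dt
            for j in range(12):
                psi[j] = sig[j] * sqdt * np.random.standard_normal()
            _drift_nb(x, t, p, W, i_per, i_tar, i_ori, lip_leak, f1)
            if rk2:
                # stochastic Heun: predictor with full noise, trapezoidal drift
                for j in range(20):
                    xp[j] = x[j] + dt * f1[j]
                for j in range(12):
                    xp[noise_idx[j]] += psi[j]
                if clamp:
                    for j in range(16, 20):
                        if xp[j] < 0.0:
                            xp[j] = 0.0
                if xp[18] > cap:
                    xp[18] = cap
                if xp[19] > cap:
                    xp[19] = cap
                _drift_nb(xp, t + dt, p, W, i_per, i_tar, i_ori, lip_leak, f2)
                for j in range(20):
                    x[j] += 0.5 * dt * (f1[j] + f2[j])
                for j in range(12):
                    x[noise_idx[j]] += psi[j]
            else:
                for j in range(20):
                    x[j] += dt * f1[j]
                for j in range(12):
                    x[noise_idx[j]] += psi[j]
            if clamp:
                if x[16] < 0.0:
                    x[16] = 0.0
                if x[17] < 0.0:
                    x[17] = 0.0
                if x[18] < 0.0:
                    x[18] = 0.0
                if x[19] < 0.0:
                    x[19] = 0.0
            if x[18] > cap:
                x[18] = cap
            if x[19] > cap:
                x[19] = cap
            ok = True
            for j in range(20):
                if not math.isfinite(x[j]):
                    ok = False
            if not ok:
                crossing[i] = -2.0
                break
            if crossing[i] < 0.0 and crossing[i] > -1.5:
                if x[18] >= theta or x[19] >= theta:
                    crossing[i] = (k + 1) * dt
                    side[i] = 0 if x[18] >= x[19] else 1
                    if record_mode == 0:
                        break
            if record_mode >= 1 and (k + 1) % rec_every == 0 \
                    and (k + 1) <= rec_steps:
                idx = (k + 1) // rec_every
                for j in range(20):
                    traj_sum[j, idx] += x[j]
                    traj_sqsum[j, idx] += x[j] * x[j]
                if record_mode == 2:
                    for j in range(6):
                        lip_full[i, j, idx] = x[j]
            if record_mode >= 1 and crossing[i] >= 0.0 \
                    and (k + 1) >= rec_steps:
                break


def _simulate_condition(params: ModelParameters, condition: TrialCondition,
                        n: int, seeds: np.ndarray, options: EngineOptions,
                        record: str) -> tuple[pd.DataFrame,
                                              Optional[ConditionTraces]]:
    """Run n trials of one condition; record in {'none','mean','full'}."""
    p = _params_vector(params)
    W = LipTopology.inhibition_matrix(params.eta_lip, params.eta_lip_decay1,
                                      params.eta_lip_decay2)
    sig = _noise_amplitudes(params, options.noise_scaling)
    ins = condition_inputs(params, condition)
    n_steps = int(round(options.t_max / options.dt))
    rec_every = int(round(options.traj_sample_ms / options.dt))
    rec_steps = int(round(options.traj_t_max / options.dt))
    record_mode = {"none": 0, "mean": 1, "full": 2}[record]
    n_grid = rec_steps // rec_every + 1

    crossing = np.empty(n)
    side = np.empty(n, dtype=np.int8)
    if record_mode >= 1:
        traj_sum = np.zeros((20, n_grid))
        traj_sqsum = np.zeros((20, n_grid))
    else:
        traj_sum = np.zeros((20, 1))
        traj_sqsum = np.zeros((20, 1))
    if record_mode == 2:
        lip_full = np.zeros((n, 6, n_grid))
    else:
        lip_full = np.zeros((1, 6, 1))

    _run_trials(p, W, sig, ins["i_per"], ins["i_tar"], ins["i_ori"],
                seeds.astype(np.uint32), n_steps, options.dt,
                options.scheme == "rk2", options.lip_leak,
                options.clamp_nonneg, record_mode, rec_every, rec_steps,
                crossing, side, traj_sum, traj_sqsum, lip_full)

    if np.any(crossing == -2.0):
        bad = int(np.nonzero(crossing == -2.0)[0][0])
        raise FloatingPointError(
            f"non-finite state in trial {bad} (seed {int(seeds[bad])}) "
            f"of condition {condition}")

    timed_out = crossing < 0
    resp = np.where(timed_out, "none", np.where(side == 0, "L", "R"))
    correct = (resp == condition.correct_side) & ~timed_out
    rt = np.where(timed_out, np.nan, crossing + params.t_0)
    trials = pd.DataFrame({
        "set_size": condition.set_size,
        "position": condition.position,
        "orientation": condition.orientation,
        "congruent": condition.congruent,
        "response_side": resp,
        "correct": correct,
        "rt_ms": rt,
        "crossing_time_ms": np.where(timed_out, np.nan, crossing),
        "timed_out": timed_out,
        "seed": seeds.astype(np.int64),
    })

    traces = None
    if record_mode >= 1:
        time_ms = np.arange(n_grid) * options.traj_sample_ms
        mean = traj_sum / n
        var = np.maximum(traj_sqsum / n - mean ** 2, 0.0)
        sem = np.sqrt(var / max(n - 1, 1))
        traces = ConditionTraces(
            condition=condition, time_ms=time_ms, mean=mean, sem=sem,
            lip_trials=lip_full if record_mode == 2 else None)
    return trials, traces


def simulate_trial(params: ModelParameters, condition: TrialCondition,
                   seed: int, options: EngineOptions = EngineOptions(),
                   record_trajectory: bool = False) -> TrialResult:
    """Integrate a single trial until threshold crossing or timeout.

    The pre-threshold latencies require ``t_max > p_delay + t_delay``.
    """
    if options.t_max <= params.p_delay + params.t_delay:
        raise ValueError("t_max must exceed p_delay + t_delay")
    seeds = np.array([seed % (2 ** 32)], dtype=np.uint64)
    record = "mean" if record_trajectory else "none"
    trials, traces = _simulate_condition(params, condition, 1, seeds,
                                         options, record)
    row = trials.iloc[0]
    return TrialResult(
        response_side=row["response_side"],
        correct=bool(row["correct"]),
        rt_ms=float(row["rt_ms"]),
        crossing_time_ms=float(row["crossing_time_ms"]),
        timed_out=bool(row["timed_out"]),
        seed=int(row["seed"]),
        condition=condition,
        trajectory_t=traces.time_ms if traces is not None else None,
        trajectory=traces.mean.T.copy() if traces is not None else None,
    )


def simulate_batch(params: ModelParameters,
                   conditions: Sequence[TrialCondition],
                   n_per_condition: int, seed: int,
                   options: EngineOptions = EngineOptions(),
                   record_trajectories: bool = False,
                   record_full: bool = False) -> BatchResult:
    """Simulate ``n_per_condition`` independent trials of each condition.

    Per-trial seeds derive reproducibly from the master ``seed`` (one
    spawned stream per condition), so a fixed seed gives a bit-identical
    BatchResult.  With ``record_trajectories`` the per-condition mean and
    SEM trajectories are accumulated on a ``traj_sample_ms`` grid;
    ``record_full`` additionally keeps every trial's LIP traces (memory
    scales with n; intended for small batches, e.g. spike synthesis).
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions))
    frames = []
    traces: dict[TrialCondition, ConditionTraces] = {}
    record = "full" if record_full else ("mean" if record_trajectories
                                         else "none")
    for cond, child in zip(conditions, children):
        seeds = child.generate_state(n_per_condition, dtype=np.uint32)
        trials, tr = _simulate_condition(params, cond, n_per_condition,
                                         seeds.astype(np.uint64), options,
                                         record)
        frames.append(trials)
        if tr is not None:
            traces[cond] = tr
    batch = BatchResult(trials=pd.concat(frames, ignore_index=True),
                        traces=traces)
    return batch
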