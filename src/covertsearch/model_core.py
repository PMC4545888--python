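"""Core definitions of the multi-area covert-search model.

The model links four populations engaged by a covert visual search task in
which a monkey finds a left- or right-facing E among distractors and reports
its orientation by releasing the left or right bar:

* **LIP** — six spatially tuned units, one per stimulus placeholder, with
  mutual inhibition that decays with distance around the display ring.
* **IT** — two feature-selective units, one per target orientation.
* **AIP** — two gated accumulators, one per response side, integrating
  excitation from IT and from the same-hemifield LIP units.
* **Motor** — two thresholded gated accumulators; the first to cross the
  threshold ``theta`` triggers the response.

Step inputs are low-pass filtered through Ornstein-Uhlenbeck processes
(synaptic filtering), and LIP/IT drive passes through a saturating
firing-rate transfer function ``phi``.  Unit activities are in kHz
throughout; times in ms with t = 0 at cue onset.

This module holds the deterministic pieces: parameter/condition containers,
the nonlinearities, the input schedules, the LIP ring topology, and the
drift (deterministic derivative + noise amplitudes) for all 20 state
variables.  Stochastic integration lives in :mod:`covertsearch.sde_engine`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields, replace
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "LIP_UNITS",
    "ORIENTATIONS",
    "FIXED",
    "ModelParameters",
    "TrialCondition",
    "LipTopology",
    "heaviside",
    "phi",
    "gate",
    "perceptual_input",
    "target_input",
    "orientation_input",
    "motor_inhibition",
    "drift",
    "state_index",
    "mirror_state",
    "load_params",
]

# Display locations, left/right hemifield by first letter, rows 1 (top) to 3
# (bottom).  The state-vector ordering everywhere in the package is:
#   0-5   X_lip   (L1, L2, L3, R1, R2, R3)
#   6-11  rho_lip (same order)
#   12-13 X_it    (E_left, E_right)
#   14-15 rho_it  (same order)
#   16-17 X_aip   (L, R)
#   18-19 X_m     (L, R)
LIP_UNITS = ("L1", "L2", "L3", "R1", "R2", "R3")
ORIENTATIONS = ("E_left", "E_right")
N_STATE = 20

_ACTIVE_LOCS = {
    2: ("L1", "R1"),
    4: ("L1", "R1", "L2", "R2"),
    6: LIP_UNITS,
}


class _Fixed:
    """Fixed model constants (not fitted)."""

    tau_lip_noise: float = 5.0  # ms, OU filter for LIP inputs
    tau_it_noise: float = 5.0  # ms, OU filter for IT inputs
    motor_cap: float = 0.150  # kHz; motor activities clamped here
    dt: float = 0.5  # ms, default integration step


FIXED = _Fixed()


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

# Fitting-time split: 18 parameters shared across subjects, 13 free per
# subject (44 free values for a two-subject joint fit).
SHARED_NAMES = (
    "tau_m", "tau_it", "tau_aip", "tau_lip",
    "eta_maipit", "eta_lip_decay1", "eta_lip_decay2", "alpha_lip",
    "w_aipm", "beta_maip", "beta_mitlip",
    "s_back", "s_ori", "c_maip",
    "k_m", "g_m", "k_aip", "g_aip",
)
PER_SUBJECT_NAMES = (
    "p_delay", "t_delay", "eta_lip",
    "w_itaip", "w_lipaip", "w_aiplip", "beta_aiplip",
    "s_lip", "s_tar", "c_it", "c_lip",
    "t_0", "theta",
)

# Config-file keys (as conventionally printed) -> dataclass field names.
_KEY_TO_FIELD = {
    "P_delay": "p_delay", "T_delay": "t_delay",
    "tau_m": "tau_m", "tau_it": "tau_it", "tau_aip": "tau_aip",
    "tau_lip": "tau_lip", "eta_maipit": "eta_maipit", "eta_lip": "eta_lip",
    "eta_lip_decay1": "eta_lip_decay1", "eta_lip_decay2": "eta_lip_decay2",
    "alpha_lip": "alpha_lip", "w_aipm": "w_aipm", "w_itaip": "w_itaip",
    "w_lipaip": "w_lipaip", "w_aiplip": "w_aiplip",
    "beta_aiplip": "beta_aiplip", "beta_maip": "beta_maip",
    "beta_mitlip": "beta_mitlip", "s_lip": "s_lip", "s_tar": "s_tar",
    "s_back": "s_back", "s_ori": "s_ori", "c_maip": "c_maip",
    "c_it": "c_it", "c_lip": "c_lip", "k_m": "k_m", "g_m": "g_m",
    "k_aip": "k_aip", "g_aip": "g_aip", "T_0": "t_0", "theta": "theta",
}
_FIELD_TO_KEY = {v: k for k, v in _KEY_TO_FIELD.items()}


@dataclass(frozen=True)
class ModelParameters:
    """The 31 fitted model parameters for one subject.

    Times and delays in ms, activities/thresholds in kHz, input strengths
    and weights dimensionless (input-current units).
    """

    p_delay: float      # perceptual delay (retina -> LIP), ms
    t_delay: float      # additional target-search delay, ms
    tau_m: float        # motor time constant, ms
    tau_it: float       # IT time constant, ms
    tau_aip: float      # AIP time constant, ms
    tau_lip: float      # LIP time constant, ms
    eta_maipit: float   # mutual inhibition within motor, AIP, IT
    eta_lip: float      # LIP mutual inhibition strength
    eta_lip_decay1: float  # inhibition decay, 2-step neighbors
    eta_lip_decay2: float  # additional decay, 3-step neighbor
    alpha_lip: float    # LIP recurrent self-excitation
    w_aipm: float       # AIP -> motor excitation
    w_itaip: float      # IT -> AIP excitation
    w_lipaip: float     # LIP -> AIP excitation (same hemifield)
    w_aiplip: float     # AIP -> LIP excitation (same hemifield)
    beta_aiplip: float  # AIP -> LIP crossed inhibition
    beta_maip: float    # motor -> AIP inhibition
    beta_mitlip: float  # motor -> IT and LIP inhibition
    s_lip: float        # perceptual input strength to LIP
    s_tar: float        # target input strength to target LIP unit
    s_back: float       # background input to LIP
    s_ori: float        # orientation input strength to IT
    c_maip: float       # noise SD, motor and AIP
    c_it: float         # noise SD, IT inputs
    c_lip: float        # noise SD, LIP inputs
    k_m: float          # motor leak
    g_m: float          # motor gate level
    k_aip: float        # AIP leak
    g_aip: float        # AIP gate level
    t_0: float          # nondecision time, ms
    theta: float        # motor response threshold, kHz

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_it", "tau_aip", "tau_lip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        for name in ("c_maip", "c_it", "c_lip"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise SD {name} must be >= 0")
        for name in ("p_delay", "t_delay", "t_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def delay_sum(self) -> float:
        """Total non-decision latency P_delay + T_delay + T_0 (ms)."""
        return self.p_delay + self.t_delay + self.t_0

    def replace(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        """Flat dict keyed by the conventional parameter names."""
        return {_FIELD_TO_KEY[f.name]: float(getattr(self, f.name))
                for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - set(_KEY_TO_FIELD)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(_KEY_TO_FIELD) - set(d)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{_KEY_TO_FIELD[k]: float(v) for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_params(subject: str) -> ModelParameters:
    """Load one of the shipped fitted parameter sets (``"m11"`` or ``"m12"``)."""
    name = subject.lower()
    if name not in ("m11", "m12"):
        raise ValueError("subject must be 'm11' or 'm12'")
    ref = importlib.resources.files("covertsearch.data") / f"params_{name}.yaml"
    with ref.open() as fh:
        return ModelParameters.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Trial conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialCondition:
    """Stimulus triplet: set size, target position, target orientation.

    A trial is *congruent* when the correct bar release is on the same side
    of the display as the target: a right-facing E in the right hemifield,
    or a left-facing E in the left hemifield.
    """

    set_size: int
    position: str
    orientation: str

    def __post_init__(self) -> None:
        if self.set_size not in _ACTIVE_LOCS:
            raise ValueError(f"set_size must be one of {sorted(_ACTIVE_LOCS)}")
        if self.position not in LIP_UNITS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.position not in _ACTIVE_LOCS[self.set_size]:
            raise ValueError(
                f"position {self.position} not displayed at set size {self.set_size}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def target_hemifield(self) -> str:
        return self.position[0]

    @property
    def correct_side(self) -> str:
        """Response side implied by orientation: right-facing E -> R bar."""
        return "R" if self.orientation == "E_right" else "L"

    @property
    def congruent(self) -> bool:
        return self.target_hemifield == self.correct_side

    def mirrored(self) -> "TrialCondition":
        pos = ("R" if self.position[0] == "L" else "L") + self.position[1]
        ori = "E_left" if self.orientation == "E_right" else "E_right"
        return TrialCondition(self.set_size, pos, ori)


# ---------------------------------------------------------------------------
# Nonlinearities
# ---------------------------------------------------------------------------


def heaviside(x):
    """Unit step: 1 for x >= 0, else 0. Rejects non-finite input."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("heaviside: non-finite input")
    out = np.where(arr >= 0.0, 1.0, 0.0)
    return out if out.ndim else float(out)


_PHI_A = 0.352
_PHI_B = 0.384
_PHI_C = 352.0
_PHI_G = 0.1


def phi(current):
    """Saturating firing-rate transfer function (output in kHz).

    phi[I] = 0.001 + 0.352 (I - 0.384) /
             (1 - exp[-352 (I - 0.384)] + 0.352 (I - 0.384) / 0.1)

    Strictly increasing and bounded in (0.001, 0.101); the removable
    singularity at I = 0.384 is filled by its limit.
    """
    I = np.asarray(current, dtype=float)
    u = I - _PHI_B
    z = _PHI_C * u
    # -expm1(-z) is accurate near z = 0; exp overflows for z << 0, where the
    # exponential dominates and phi -> 0.001.
    with np.errstate(over="ignore"):
        denom = -np.expm1(-np.clip(z, -700.0, None)) + (_PHI_A / _PHI_G) * u
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.001 + _PHI_A * u / denom
    # removable singularity: limit 0.001 + 0.352/(352 + 3.52)
    limit = 0.001 + _PHI_A / (_PHI_C + _PHI_A / _PHI_G)
    val = np.where(np.abs(z) < 1e-12, limit, val)
    val = np.where(z <= -700.0, 0.001, val)
    return val if val.ndim else float(val)


def gate(current, g):
    """Piecewise-linear gate: I - g if positive, else 0."""
    out = np.maximum(np.asarray(current, dtype=float) - g, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Input schedules
# ---------------------------------------------------------------------------


def perceptual_input(set_size: int, location: str, s_lip: float = 1.0) -> float:
    """Perceptual drive to one LIP unit: s_lip at displayed locations, else 0."""
    if location not in LIP_UNITS:
        raise ValueError(f"unknown location {location!r}")
    if set_size not in _ACTIVE_LOCS:
        raise ValueError(f"set_size must be one of {sorted(_ACTIVE_LOCS)}")
    return s_lip if location in _ACTIVE_LOCS[set_size] else 0.0


def target_input(position: str, location: str, s_tar: float = 1.0) -> float:
    """Target drive: s_tar to the unit whose RF holds the target, else 0."""
    if location not in LIP_UNITS or position not in LIP_UNITS:
        raise ValueError("unknown location label")
    return s_tar if position == location else 0.0


def orientation_input(orientation: str, it_unit: str, s_ori: float = 1.0) -> float:
    """Orientation drive to IT: s_ori on the matching orientation unit."""
    if orientation not in ORIENTATIONS or it_unit not in ORIENTATIONS:
        raise ValueError("unknown orientation label")
    return s_ori if orientation == it_unit else 0.0


def motor_inhibition(x_m: Iterable[float], weight: float) -> float:
    """Global motor feedback: weight * (X_m,L + X_m,R)."""
    xl, xr = x_m
    return weight * (xl + xr)


# ---------------------------------------------------------------------------
# LIP ring topology
# ---------------------------------------------------------------------------


class LipTopology:
    """Ring arrangement of the six LIP receptive fields.

    Placeholders sit on the cycle L1 - R1 - R2 - R3 - L3 - L2 - L1; mutual
    inhibition between two units decays with their ring distance: eta_lip at
    1 step, eta_lip * decay1 at 2 steps, eta_lip * decay1 * decay2 at 3.
    """

    RING = ("L1", "R1", "R2", "R3", "L3", "L2")

    @classmethod
    def ring_distance(cls, a: str, b: str) -> int:
        ia, ib = cls.RING.index(a), cls.RING.index(b)
        d = abs(ia - ib)
        return min(d, len(cls.RING) - d)

    @classmethod
    def neighbors(cls, unit: str, steps: int) -> tuple[str, ...]:
        return tuple(u for u in LIP_UNITS
                     if u != unit and cls.ring_distance(unit, u) == steps)

    @classmethod
    def inhibition_matrix(cls, eta_lip: float, decay1: float,
                          decay2: float) -> np.ndarray:
        """6x6 matrix W with W[i, j] the inhibition unit j exerts on unit i."""
        w_by_dist = {1: eta_lip, 2: eta_lip * decay1, 3: eta_lip * decay1 * decay2}
        W = np.zeros((6, 6))
        for i, a in enumerate(LIP_UNITS):
            for j, b in enumerate(LIP_UNITS):
                if a != b:
                    W[i, j] = w_by_dist[cls.ring_distance(a, b)]
        return W


# ---------------------------------------------------------------------------
# State indexing helpers
# ---------------------------------------------------------------------------

_IDX = {}
for _i, _u in enumerate(LIP_UNITS):
    _IDX[("x_lip", _u)] = _i
    _IDX[("rho_lip", _u)] = 6 + _i
for _i, _o in enumerate(ORIENTATIONS):
    _IDX[("x_it", _o)] = 12 + _i
    _IDX[("rho_it", _o)] = 14 + _i
_IDX[("x_aip", "L")] = 16
_IDX[("x_aip", "R")] = 17
_IDX[("x_m", "L")] = 18
_IDX[("x_m", "R")] = 19


def state_index(kind: str, label: str) -> int:
    """Index of one state variable in the 20-vector (see module docstring)."""
    return _IDX[(kind, label)]


# permutation that swaps the hemifields (and orientations / sides) of a state
_MIRROR = np.arange(N_STATE)
for _l, _r in (("L1", "R1"), ("L2", "R2"), ("L3", "R3")):
    for _kind in ("x_lip", "rho_lip"):
        _MIRROR[_IDX[(_kind, _l)]] = _IDX[(_kind, _r)]
        _MIRROR[_IDX[(_kind, _r)]] = _IDX[(_kind, _l)]
for _kind in ("x_it", "rho_it"):
    _MIRROR[_IDX[(_kind, "E_left")]] = _IDX[(_kind, "E_right")]
    _MIRROR[_IDX[(_kind, "E_right")]] = _IDX[(_kind, "E_left")]
for _kind in ("x_aip", "x_m"):
    _MIRROR[_IDX[(_kind, "L")]] = _IDX[(_kind, "R")]
    _MIRROR[_IDX[(_kind, "R")]] = _IDX[(_kind, "L")]


def mirror_state(state: np.ndarray) -> np.ndarray:
    """Swap left and right hemifields throughout the state vector."""
    return np.asarray(state)[..., _MIRROR]


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------


def condition_inputs(params: ModelParameters,
                     condition: TrialCondition) -> dict[str, np.ndarray]:
    """Precomputed per-unit input strengths for one trial condition."""
    i_per = np.array([perceptual_input(condition.set_size, u, params.s_lip)
                      for u in LIP_UNITS])
    i_tar = np.array([target_input(condition.position, u, params.s_tar)
                      for u in LIP_UNITS])
    i_ori = np.array([orientation_input(condition.orientation, o, params.s_ori)
                      for o in ORIENTATIONS])
    return {"i_per": i_per, "i_tar": i_tar, "i_ori": i_ori}


def drift(state: np.ndarray, params: ModelParameters,
          condition: TrialCondition, t: float,
          lip_leak: bool = True,
          noise_scaling: str = "tau") -> tuple[np.ndarray, np.ndarray]:
    """Deterministic derivative and noise amplitudes for the 20-SDE system.

    Parameters
    ----------
    state
        Array of shape (..., 20) in the module's state ordering.
    t
        Time in ms from cue onset; the perceptual input switches on at
        ``p_delay`` and the target/orientation inputs at
        ``p_delay + t_delay``.
    lip_leak
        Include the -X leak in the LIP rate equations (default), matching
        the IT form; if False, use the literal leak-free form.
    noise_scaling
        "tau": amplitude c/tau for an equation written tau dX = f dt + c xi
        (literal reading); "sqrt_tau": amplitude c/sqrt(tau).

    Returns
    -------
    f, sigma
        ``f`` with the same shape as ``state`` (d state / dt, per ms) and
        ``sigma`` of shape (20,): the white-noise amplitude of each
        equation, such that one Euler step adds ``sigma * sqrt(dt) * N(0,1)``.
    """
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != N_STATE:
        raise ValueError(f"state must have {N_STATE} components")
    p = params
    ins = condition_inputs(p, condition)

    x_lip = s[..., 0:6]
    rho_lip = s[..., 6:12]
    x_it = s[..., 12:14]
    rho_it = s[..., 14:16]
    x_aip = s[..., 16:18]
    x_m = s[..., 18:20]

    i_mi = p.beta_mitlip * (x_m[..., 0] + x_m[..., 1])
    i_maip = p.beta_maip * (x_m[..., 0] + x_m[..., 1])

    W = LipTopology.inhibition_matrix(p.eta_lip, p.eta_lip_decay1,
                                      p.eta_lip_decay2)
    inh = x_lip @ W.T

    # AIP drive onto LIP: same-hemifield excitation, crossed inhibition.
    aip_L = x_aip[..., 0:1]
    aip_R = x_aip[..., 1:2]
    aip_drive = np.concatenate([
        np.repeat(p.w_aiplip * aip_L - p.beta_aiplip * aip_R, 3, axis=-1),
        np.repeat(p.w_aiplip * aip_R - p.beta_aiplip * aip_L, 3, axis=-1),
    ], axis=-1)

    lip_arg = (aip_drive + p.alpha_lip * x_lip - i_mi[..., None] - inh
               + rho_lip)
    f_lip = phi(lip_arg)
    if lip_leak:
        f_lip = f_lip - x_lip
    f_lip = f_lip / p.tau_lip

    on_per = heaviside(t - p.p_delay)
    on_tar = heaviside(t - p.p_delay - p.t_delay)
    f_rho_lip = (-rho_lip + ins["i_per"] * on_per + ins["i_tar"] * on_tar
                 + p.s_back) / FIXED.tau_lip_noise

    it_arg = (rho_it - p.eta_maipit * x_it[..., ::-1] - i_mi[..., None])
    f_it = (phi(it_arg) - x_it) / p.tau_it

    f_rho_it = (-rho_it + ins["i_ori"] * on_tar) / FIXED.tau_it_noise

    # E_left drives the left AIP unit, E_right the right one.
    lip_sum_L = x_lip[..., 0:3].sum(axis=-1)
    lip_sum_R = x_lip[..., 3:6].sum(axis=-1)
    aip_in = np.stack([
        p.w_itaip * x_it[..., 0] + p.w_lipaip * lip_sum_L,
        p.w_itaip * x_it[..., 1] + p.w_lipaip * lip_sum_R,
    ], axis=-1) - i_maip[..., None]
    f_aip = (-p.k_aip * x_aip - p.eta_maipit * x_aip[..., ::-1]
             + gate(aip_in, p.g_aip)) / p.tau_aip

    f_m = (-p.k_m * x_m - p.eta_maipit * x_m[..., ::-1]
           + gate(p.w_aipm * x_aip, p.g_m)) / p.tau_m

    f = np.concatenate([f_lip, f_rho_lip, f_it, f_rho_it, f_aip, f_m],
                       axis=-1)

    if noise_scaling == "tau":
        denom = lambda tau: tau
    elif noise_scaling == "sqrt_tau":
        denom = lambda tau: np.sqrt(tau)
    else:
        raise ValueError("noise_scaling must be 'tau' or 'sqrt_tau'")
    sigma = np.zeros(N_STATE)
    sigma[6:12] = p.c_lip / denom(FIXED.tau_lip_noise)
    sigma[14:16] = p.c_it / denom(FIXED.tau_it_noise)
    sigma[16:18] = p.c_maip / denom(p.tau_aip)
    sigma[18:20] = p.c_maip / denom(p.tau_m)
    return f, sigma
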