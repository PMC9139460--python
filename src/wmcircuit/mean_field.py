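"""E/I mean-field population model with synaptic state variables.

One population pair (pyramidal group E, interneuron group I) is described
by its mean firing rates ``r_E``, ``r_I`` and four synaptic activation
variables ``s_EE, s_EI, s_IE, s_II``:

    tau_E * dr_E/dt = -r_E + f(J_EE s_EE - J_EI s_EI + J_EO i(t))
    tau_I * dr_I/dt = -r_I + f(J_IE s_IE - J_II s_II)
    tau_ij * ds_ij/dt = -s_ij + r_j        for i, j in {E, I}

``s_ij`` is the synapse onto element ``i`` from element ``j`` and relaxes
toward the presynaptic rate ``r_j`` with its own time constant; the slow
E-to-E kinetics (``tau_EE = 100`` ms, NMDA-like) against fast inhibitory
kinetics implement negative-derivative feedback at the population level.

``f`` is the thresholded Naka-Rushton steady-state response

    f(x) = M (x - x_theta)^2 / (x_half^2 + (x - x_theta)^2) * h(x - x_theta)

with Heaviside convention ``h(0) = 0``, so the output is exactly 0 up to
and including the threshold and saturates at ``M`` for large input.

Defaults: M = 100, x_theta = 30, x_half = 30, tau_E = 20 ms, tau_I = 10 ms,
tau_EE/EI/IE/II = 100/25/10/10 ms, intra-unit J_EE/EI/IE/II = 300/450/900/900
and inter-unit 150/300/600/600 (used by :mod:`wmcircuit.set_network`), with
the external-input gain J_EO restricted to [0, 6000].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .rate_models import DEFAULT_DT, StimulusProtocol

CONNECTIONS = ("EE", "EI", "IE", "II")

DEFAULT_TAU_SYN: Dict[str, float] = {"EE": 100.0, "EI": 25.0, "IE": 10.0, "II": 10.0}
DEFAULT_J_INTRA: Dict[str, float] = {"EE": 300.0, "EI": 450.0, "IE": 900.0, "II": 900.0}
DEFAULT_J_INTER: Dict[str, float] = {"EE": 150.0, "EI": 300.0, "IE": 600.0, "II": 600.0}
J_EO_RANGE = (0.0, 6000.0)


@dataclass(frozen=True)
class NakaRushtonParams:
    """Steady-state transfer function parameters: maximal response ``m_max``,
    input threshold ``x_theta`` and half-activation ``x_half``
    (``f(x_theta + x_half) = m_max / 2``)."""

    m_max: float = 100.0
    x_theta: float = 30.0
    x_half: float = 30.0

    def __post_init__(self) -> None:
        if self.m_max <= 0:
            raise ValueError(f"m_max must be > 0, got {self.m_max}")
        if self.x_half <= 0:
            raise ValueError(f"x_half must be > 0, got {self.x_half}")


@dataclass(frozen=True)
class MeanFieldParams:
    """Time constants and synaptic weights of the E/I population model."""

    tau_e: float = 20.0
    tau_i: float = 10.0
    tau_syn: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAU_SYN))
    j_intra: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_J_INTRA))
    j_inter: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_J_INTER))
    j_eo: float = 3000.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("tau_e and tau_i must be > 0")
        for key in CONNECTIONS:
            if key not in self.tau_syn:
                raise ValueError(f"tau_syn missing connection {key!r}")
            if self.tau_syn[key] <= 0:
                raise ValueError(f"tau_syn[{key!r}] must be > 0")
            for jmap, name in ((self.j_intra, "j_intra"), (self.j_inter, "j_inter")):
                if key not in jmap:
                    raise ValueError(f"{name} missing connection {key!r}")
                if jmap[key] < 0:
                    raise ValueError(f"{name}[{key!r}] must be >= 0")
        lo, hi = J_EO_RANGE
        if not (lo <= self.j_eo <= hi):
            raise ValueError(
                f"j_eo={self.j_eo} outside the admissible range [{lo}, {hi}]")

    @property
    def min_tau(self) -> float:
        return min(self.tau_e, self.tau_i, *self.tau_syn.values())


@dataclass
class PopulationState:
    """State of one E/I population: rates plus the four synaptic variables."""

    r_e: float = 0.0
    r_i: float = 0.0
    s: Dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in CONNECTIONS})

    def copy(self) -> "PopulationState":
        return PopulationState(r_e=self.r_e, r_i=self.r_i, s=dict(self.s))

    def as_vector(self) -> np.ndarray:
        return np.array([self.r_e, self.r_i] + [self.s[k] for k in CONNECTIONS])


def naka_rushton(x, p: NakaRushtonParams = NakaRushtonParams()):
    """Thresholded Naka-Rushton steady-state response.

    Returns 0 for ``x <= x_theta`` and
    ``m_max (x-x_theta)^2 / (x_half^2 + (x-x_theta)^2)`` above threshold.
    Monotone nondecreasing and bounded by ``m_max``; accepts scalars or
    arrays.
    """
    x = np.asarray(x, dtype=float)
    d = x - p.x_theta
    with np.errstate(over="ignore", invalid="ignore"):
        above = p.m_max * d * d / (p.x_half ** 2 + d * d)
    out = np.where(d > 0, above, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _presynaptic_rate(key: str, r_e: float, r_i: float) -> float:
    return r_e if key[1] == "E" else r_i


def step_population(state: PopulationState, i_ext: float, p: MeanFieldParams,
                    nr: NakaRushtonParams = NakaRushtonParams(),
                    dt: float = DEFAULT_DT) -> PopulationState:
    """One forward-Euler step of all six state variables of one population.

    ``i_ext`` is the external stimulus-plus-noise current ``i(t)``; it enters
    the excitatory population scaled by ``j_eo``.  Raises ``ValueError`` as
    soon as any state variable becomes non-finite, naming the variable.
    """
    if dt > p.min_tau / 5 + 1e-12:
        raise ValueError(f"dt={dt} too large; require dt <= min(tau)/5 = {p.min_tau / 5}")
    x_e = (p.j_intra["EE"] * state.s["EE"] - p.j_intra["EI"] * state.s["EI"]
           + p.j_eo * i_ext)
    x_i = p.j_intra["IE"] * state.s["IE"] - p.j_intra["II"] * state.s["II"]
    new = PopulationState(
        r_e=state.r_e + dt * (-state.r_e + naka_rushton(x_e, nr)) / p.tau_e,
        r_i=state.r_i + dt * (-state.r_i + naka_rushton(x_i, nr)) / p.tau_i,
        s={k: state.s[k] + dt * (-state.s[k]
                                 + _presynaptic_rate(k, state.r_e, state.r_i))
           / p.tau_syn[k]
           for k in CONNECTIONS},
    )
    for name, value in [("r_e", new.r_e), ("r_i", new.r_i)] + [
            (f"s_{k}", new.s[k]) for k in CONNECTIONS]:
        if not np.isfinite(value):
            raise ValueError(f"state variable {name} became non-finite")
    return new


@dataclass
class PopulationTrace:
    """Trajectory of a single population on a uniform time grid."""

    times: np.ndarray
    r_e: np.ndarray
    r_i: np.ndarray
    s: Dict[str, np.ndarray]

    def final_state(self) -> PopulationState:
        return PopulationState(r_e=float(self.r_e[-1]), r_i=float(self.r_i[-1]),
                               s={k: float(self.s[k][-1]) for k in CONNECTIONS})


def simulate_population(init: PopulationState, stim: StimulusProtocol,
                        p: MeanFieldParams = MeanFieldParams(),
                        nr: NakaRushtonParams = NakaRushtonParams(),
                        dt: float = DEFAULT_DT) -> PopulationTrace:
    """Integrate one population over the stimulus protocol.

    Deterministic given the protocol's noise seed: two calls with identical
    arguments produce bitwise-identical trajectories.
    """
    drive = stim.sample(dt)
    n = len(drive)
    times = np.arange(n) * dt
    r_e = np.empty(n); r_i = np.empty(n)
    s = {k: np.empty(n) for k in CONNECTIONS}
    state = init.copy()
    for k in range(n):
        r_e[k] = state.r_e
        r_i[k] = state.r_i
        for key in CONNECTIONS:
            s[key][k] = state.s[key]
        state = step_population(state, drive[k], p, nr, dt)
    return PopulationTrace(times=times, r_e=r_e, r_i=r_i, s=s)
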