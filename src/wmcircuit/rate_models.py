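"""Single-unit feedback memory models.

Three linear firing-rate units, each describing how a transient input
current ``I(t)`` can be held after its offset:

* **Positive feedback** — ``tau * dr/dt = -(1 - w_pos) * r + I(t)``.
  Feedback of strength ``w_pos`` replaces the membrane leak; the unit is
  balanced (drift-free) exactly at ``w_pos = 1``, decays for ``w_pos < 1``
  and grows exponentially for ``w_pos > 1``.

* **Negative-derivative feedback** — a fast/slow pair
  ``tau * drE/dt = -w_pos * rE + I(t)`` and
  ``tau * drI/dt = -w_der * rI + I(t)``.  The pointwise difference
  ``rE - rI`` isolates the corrective, derivative-like component that
  arises when excitatory-to-excitatory kinetics are slower than
  excitatory-to-inhibitory kinetics.

* **Hybrid (HPNF)** — ``tau * dr/dt = -r + w_pos * r - w_der * dr/dt + I(t)``,
  rearranged before integration to
  ``(tau + w_der) * dr/dt = -(1 - w_pos) * r + I(t)``.  The derivative
  feedback inflates the effective time constant to
  ``(tau + w_der) / (1 - w_pos)``, so mistuned positive feedback drifts far
  more slowly.  Note that after the rearrangement ``w_der`` adds to ``tau``
  and therefore carries time-like units (ms) even though it originates as a
  synaptic strength.

All three models are linear; rectification only enters downstream through
the population transfer function (see :mod:`wmcircuit.mean_field`).
Integration is forward Euler at ``dt = 0.1`` ms by default, with a
fixed-step RK4 integrator available as a high-order reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

DEFAULT_DT = 0.1  # ms
#: Rates beyond this magnitude are treated as numerical blow-up.
OVERFLOW_LIMIT = 1e12


@dataclass(frozen=True)
class FeedbackParams:
    """Parameters of a single-unit feedback memory model.

    Parameters
    ----------
    tau:
        Intrinsic time constant in ms, > 0.
    w_pos:
        Dimensionless positive-feedback synaptic strength, >= 0.
    w_der:
        Negative-derivative feedback strength, >= 0.  Time-like (ms) in the
        hybrid model, where it adds to ``tau``.
    """

    tau: float = 20.0
    w_pos: float = 1.0
    w_der: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be finite and > 0, got {self.tau}")
        for name in ("w_pos", "w_der"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the input current, drawn per time step."""

    std: float
    seed: int

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError(f"noise std must be >= 0, got {self.std}")


@dataclass(frozen=True)
class StimulusProtocol:
    """A list of timed rectangular current pulses plus optional seeded noise.

    Each pulse is an ``(onset_ms, duration_ms, amplitude)`` triple.  Pulses
    may overlap; their amplitudes add.
    """

    pulses: Tuple[Tuple[float, float, float], ...]
    total_duration: float
    noise: Optional[NoiseSpec] = None

    def __init__(self, pulses: Sequence[Sequence[float]], total_duration: float,
                 noise: Optional[NoiseSpec] = None):
        pulses = tuple(tuple(float(x) for x in p) for p in pulses)
        for onset, duration, _amp in pulses:
            if onset < 0:
                raise ValueError(f"pulse onset must be >= 0, got {onset}")
            if duration <= 0:
                raise ValueError(f"pulse duration must be > 0, got {duration}")
            if onset + duration > total_duration + 1e-9:
                raise ValueError(
                    f"pulse [{onset}, {onset + duration}] extends past "
                    f"total_duration={total_duration}")
        if total_duration <= 0:
            raise ValueError("total_duration must be > 0")
        object.__setattr__(self, "pulses", pulses)
        object.__setattr__(self, "total_duration", float(total_duration))
        object.__setattr__(self, "noise", noise)

    def sample(self, dt: float) -> np.ndarray:
        """Input current on the uniform grid ``t_k = k * dt``."""
        n = int(round(self.total_duration / dt))
        drive = np.zeros(n)
        t = np.arange(n) * dt
        for onset, duration, amp in self.pulses:
            drive[(t >= onset) & (t < onset + duration)] += amp
        if self.noise is not None and self.noise.std > 0:
            rng = np.random.default_rng(self.noise.seed)
            drive = drive + rng.normal(0.0, self.noise.std, n)
        return drive


@dataclass
class RateTrace:
    """A firing-rate time series on a uniform grid.

    ``overflow`` flags trajectories that left the representable range
    (e.g. runaway positive feedback over a long horizon); the trace is still
    returned so the divergence can be inspected.
    """

    times: np.ndarray
    rates: np.ndarray
    overflow: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.times.shape != self.rates.shape:
            raise ValueError("times and rates must have the same length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("times must increase with a constant step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


def _integrate_linear(decay: float, tau_eff: float, drive: np.ndarray,
                      dt: float, r0: float, method: str) -> np.ndarray:
    """Integrate ``tau_eff * dr/dt = -decay * r + I(t)`` on the drive grid.

    ``drive`` is piecewise-constant over each step, which makes the RK4
    scheme exact for this linear ODE up to rounding.
    """
    n = len(drive)
    r = np.empty(n + 1)
    r[0] = r0
    a = -decay / tau_eff
    if method == "euler":
        for k in range(n):
            r[k + 1] = r[k] + dt * (a * r[k] + drive[k] / tau_eff)
    elif method == "rk4":
        for k in range(n):
            b = drive[k] / tau_eff

            def f(x: float) -> float:
                return a * x + b

            k1 = f(r[k])
            k2 = f(r[k] + 0.5 * dt * k1)
            k3 = f(r[k] + 0.5 * dt * k2)
            k4 = f(r[k] + dt * k3)
            r[k + 1] = r[k] + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return r[:-1]


def _check_dt(dt: float, tau: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt > tau / 10 + 1e-12:
        raise ValueError(
            f"dt={dt} too large for explicit integration; require dt <= tau/10 = {tau / 10}")


def _finish(times: np.ndarray, rates: np.ndarray) -> RateTrace:
    overflow = bool(np.any(~np.isfinite(rates)) or np.any(np.abs(rates) > OVERFLOW_LIMIT))
    return RateTrace(times=times, rates=rates, overflow=overflow)


def simulate_positive_feedback(params: FeedbackParams, stim: StimulusProtocol,
                               dt: float = DEFAULT_DT, r0: float = 0.0,
                               method: str = "euler") -> RateTrace:
    """Integrate the positive-feedback unit ``tau dr/dt = -(1-w_pos) r + I``."""
    _check_dt(dt, params.tau)
    drive = stim.sample(dt)
    times = np.arange(len(drive)) * dt
    rates = _integrate_linear(1.0 - params.w_pos, params.tau, drive, dt, r0, method)
    return _finish(times, rates)


def simulate_derivative_feedback(params: FeedbackParams, stim: StimulusProtocol,
                                 dt: float = DEFAULT_DT,
                                 r0: Tuple[float, float] = (0.0, 0.0),
                                 method: str = "euler",
                                 ) -> Tuple[RateTrace, RateTrace, RateTrace]:
    """Integrate the fast/slow pair and return ``(r_E, r_I, r_E - r_I)``.

    The excitatory trace decays with strength ``w_pos``, the inhibitory one
    with ``w_der``; their difference is the derivative-feedback signal.
    """
    _check_dt(dt, params.tau)
    drive = stim.sample(dt)
    times = np.arange(len(drive)) * dt
    r_e = _integrate_linear(params.w_pos, params.tau, drive, dt, r0[0], method)
    r_i = _integrate_linear(params.w_der, params.tau, drive, dt, r0[1], method)
    return _finish(times, r_e), _finish(times, r_i), _finish(times, r_e - r_i)


def simulate_hpnf(params: FeedbackParams, stim: StimulusProtocol,
                  dt: float = DEFAULT_DT, r0: float = 0.0,
                  method: str = "euler") -> RateTrace:
    """Integrate the hybrid unit ``(tau + w_der) dr/dt = -(1-w_pos) r + I``."""
    tau_eff = params.tau + params.w_der
    if tau_eff <= 0:
        raise ValueError("tau + w_der must be > 0")
    _check_dt(dt, params.tau)
    drive = stim.sample(dt)
    times = np.arange(len(drive)) * dt
    rates = _integrate_linear(1.0 - params.w_pos, tau_eff, drive, dt, r0, method)
    return _finish(times, rates)


def effective_time_constant(params: FeedbackParams) -> float:
    """Relaxation time constant ``(tau + w_der) / (1 - w_pos)`` of the hybrid
    unit; ``inf`` at exact balance (``w_pos = 1``)."""
    if params.w_pos >= 1.0:
        return np.inf
    return (params.tau + params.w_der) / (1.0 - params.w_pos)
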