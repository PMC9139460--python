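"""The SET storage network: N coupled self-sustaining units (NSSUs).

A SET is a bank of ``n_units`` E/I populations (each the mean-field model
of :mod:`wmcircuit.mean_field`), coupled all-to-all: connections inside a
unit use the intra-unit weights, connections between units the (halved)
inter-unit weights.  One unit — the *basic unit*, by default the fifth —
receives the external stimulus through its ``J_EO`` channel; the remaining
*backup units* are driven only through the coupling and hold a redundant
copy of the stored signal.

The module implements the two protocols used to size the bank:

* :func:`sweep_nssu_counts` — simulate the same storage protocol for a
  range of unit counts and classify each mean-rate trace as stable or not
  (windowed-drift criterion with a minimum-activity floor);
* :func:`perturb_and_measure` — transiently scale one synaptic weight
  (e.g. +5 % of J_EE for 2 % of the run) after storage and measure how far
  the mean rate departs from the unperturbed reference trajectory and
  whether it returns to it.

A note on what the sweep can show: with the default weights the summed
recurrent drive onto any excitatory population is net inhibitory for every
bank size (the effective E-to-E minus I-to-E weight is -150 per unit), so
post-stimulus activity relaxes back to rest rather than holding a plateau;
the stability classifier reports this honestly via its activity floor.
See docs/methods.md for the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mean_field import (CONNECTIONS, MeanFieldParams, NakaRushtonParams,
                         naka_rushton)
from .rate_models import DEFAULT_DT, StimulusProtocol

N_UNITS_RANGE = (2, 12)
STATE_VARS_PER_UNIT = 6

PERTURBATION_TARGETS = ("J_EE", "J_EI", "J_IE", "J_II")


@dataclass(frozen=True)
class SetConfig:
    """Configuration of a SET bank.

    ``basic_index`` is 1-based; ``None`` selects the fifth unit (or the last
    one for banks smaller than five).  ``stimulate`` chooses whether the
    external input drives only the basic unit (default) or every unit.
    """

    n_units: int = 8
    basic_index: Optional[int] = None
    coupling: Optional[Dict[str, float]] = None
    stimulate: str = "basic"

    def __post_init__(self) -> None:
        lo, hi = N_UNITS_RANGE
        if not (lo <= self.n_units <= hi):
            raise ValueError(
                f"n_units={self.n_units} outside the supported range [{lo}, {hi}]")
        if self.basic_index is not None and not (1 <= self.basic_index <= self.n_units):
            raise ValueError(
                f"basic_index={self.basic_index} must lie in [1, {self.n_units}]")
        if self.stimulate not in ("basic", "all"):
            raise ValueError("stimulate must be 'basic' or 'all'")
        if self.coupling is not None:
            for key in CONNECTIONS:
                if key not in self.coupling:
                    raise ValueError(f"coupling missing connection {key!r}")

    @property
    def basic(self) -> int:
        """0-based index of the basic unit."""
        if self.basic_index is not None:
            return self.basic_index - 1
        return min(5, self.n_units) - 1


@dataclass
class SetSystem:
    """A built SET: configuration plus resolved parameters.

    The state is a bank of ``6 * n_units`` variables
    (r_E, r_I, s_EE, s_EI, s_IE, s_II per unit).
    """

    cfg: SetConfig
    params: MeanFieldParams
    nr: NakaRushtonParams

    @property
    def n_state_variables(self) -> int:
        return STATE_VARS_PER_UNIT * self.cfg.n_units

    @property
    def j_inter(self) -> Dict[str, float]:
        return dict(self.cfg.coupling) if self.cfg.coupling is not None \
            else dict(self.params.j_inter)


@dataclass
class SetTrace:
    """Mean excitatory rate across units plus per-unit traces."""

    times: np.ndarray
    mean_rate: np.ndarray
    unit_rates: np.ndarray  # shape (n_units, n_steps)
    unit_rates_i: np.ndarray


@dataclass(frozen=True)
class StabilityCriterion:
    """Windowed-drift plateau criterion.

    The trace is stable when the mean rate over the last ``window_fraction``
    of the run differs from the mean over the preceding equal window by less
    than ``drift_tol`` (relative) and exceeds the activity ``floor``.
    """

    drift_tol: float = 0.02
    floor: float = 1.0
    window_fraction: float = 0.1


@dataclass
class StabilityReport:
    n_units: int
    stable: bool
    plateau_rate: float
    drift_metric: float


@dataclass(frozen=True)
class PerturbationSpec:
    """Transient multiplicative disturbance of one synaptic weight.

    During ``[onset, onset + window_fraction * horizon)`` the target weight
    (both its intra- and inter-unit values) is scaled by ``1 + magnitude``
    and restored afterwards — a rectangular envelope at the stated maximum
    intensity.
    """

    target: str = "J_EE"
    magnitude: float = 0.05
    window_fraction: float = 0.02
    onset: float = 400.0

    def __post_init__(self) -> None:
        if self.target not in PERTURBATION_TARGETS:
            raise ValueError(
                f"target must be one of {PERTURBATION_TARGETS}, got {self.target!r}")
        if not (0 <= self.magnitude <= 1):
            raise ValueError("magnitude must lie in [0, 1]")
        if not (0 < self.window_fraction < 1):
            raise ValueError("window_fraction must lie in (0, 1)")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


@dataclass
class PerturbationResult:
    """Max deviation of the mean rate from the unperturbed reference, and
    whether the trace re-enters the tolerance band by the end of the run."""

    metric: float
    recovery: bool
    deviation: np.ndarray
    times: np.ndarray


def build_set(cfg: SetConfig, p: Optional[MeanFieldParams] = None,
              nr: Optional[NakaRushtonParams] = None) -> SetSystem:
    """Assemble a coupled SET system description."""
    return SetSystem(cfg=cfg, params=p or MeanFieldParams(),
                     nr=nr or NakaRushtonParams())


def _integrate(system: SetSystem, stim: StimulusProtocol, dt: float,
               perturb: Optional[Tuple[str, float, float, float]] = None
               ) -> SetTrace:
    """Vectorized forward-Euler integration of the coupled bank.

    ``perturb`` is ``(connection_key, magnitude, t_start, t_stop)``; during
    the window both intra- and inter-unit values of that connection are
    scaled by ``1 + magnitude``.
    """
    cfg, p, nr = system.cfg, system.params, system.nr
    if dt <= 0 or dt > p.min_tau / 5 + 1e-12:
        raise ValueError(f"dt={dt} must be in (0, min(tau)/5]")
    n = cfg.n_units
    drive = stim.sample(dt)
    n_steps = len(drive)
    times = np.arange(n_steps) * dt

    j_in = {k: p.j_intra[k] for k in CONNECTIONS}
    j_x = system.j_inter

    r_e = np.zeros(n); r_i = np.zeros(n)
    s = {k: np.zeros(n) for k in CONNECTIONS}
    unit_rates = np.empty((n, n_steps))
    unit_rates_i = np.empty((n, n_steps))
    mean_rate = np.empty(n_steps)

    stim_mask = np.zeros(n)
    if cfg.stimulate == "all":
        stim_mask[:] = 1.0
    else:
        stim_mask[cfg.basic] = 1.0

    for k in range(n_steps):
        scale = {key: 1.0 for key in CONNECTIONS}
        if perturb is not None:
            key, mag, t0, t1 = perturb
            if t0 <= times[k] < t1:
                scale[key] = 1.0 + mag
        i_ext = drive[k] * stim_mask
        tot = {key: s[key].sum() for key in CONNECTIONS}
        x_e = (scale["EE"] * (j_in["EE"] * s["EE"] + j_x["EE"] * (tot["EE"] - s["EE"]))
               - scale["EI"] * (j_in["EI"] * s["EI"] + j_x["EI"] * (tot["EI"] - s["EI"]))
               + p.j_eo * i_ext)
        x_i = (scale["IE"] * (j_in["IE"] * s["IE"] + j_x["IE"] * (tot["IE"] - s["IE"]))
               - scale["II"] * (j_in["II"] * s["II"] + j_x["II"] * (tot["II"] - s["II"])))
        unit_rates[:, k] = r_e
        unit_rates_i[:, k] = r_i
        mean_rate[k] = r_e.mean()
        r_e = r_e + dt * (-r_e + naka_rushton(x_e, nr)) / p.tau_e
        r_i = r_i + dt * (-r_i + naka_rushton(x_i, nr)) / p.tau_i
        pre = {"EE": unit_rates[:, k], "EI": unit_rates_i[:, k],
               "IE": unit_rates[:, k], "II": unit_rates_i[:, k]}
        for key in CONNECTIONS:
            s[key] = s[key] + dt * (-s[key] + pre[key]) / p.tau_syn[key]
        if not (np.all(np.isfinite(r_e)) and np.all(np.isfinite(r_i))):
            raise ValueError(f"rate became non-finite at t={times[k]:.1f} ms")
    return SetTrace(times=times, mean_rate=mean_rate,
                    unit_rates=unit_rates, unit_rates_i=unit_rates_i)


def simulate_set(system: SetSystem, stim: StimulusProtocol,
                 dt: float = DEFAULT_DT) -> SetTrace:
    """Simulate the SET bank under a stimulus protocol."""
    return _integrate(system, stim, dt)


def default_storage_protocol(total_ms: float = 2000.0, stim_ms: float = 200.0,
                             amplitude: float = 1.0) -> StimulusProtocol:
    """The standard storage protocol: one pulse at run start."""
    return StimulusProtocol(pulses=[(0.0, stim_ms, amplitude)],
                            total_duration=total_ms)


def classify_stability(trace: SetTrace,
                       criterion: StabilityCriterion = StabilityCriterion(),
                       n_units: Optional[int] = None) -> StabilityReport:
    """Apply the windowed-drift plateau criterion to a mean-rate trace."""
    m = len(trace.mean_rate)
    w = max(1, int(round(criterion.window_fraction * m)))
    last = float(trace.mean_rate[-w:].mean())
    prev = float(trace.mean_rate[-2 * w:-w].mean())
    if last > 0:
        drift = abs(last - prev) / last
    else:
        drift = np.inf
    stable = bool(drift < criterion.drift_tol and last > criterion.floor)
    return StabilityReport(
        n_units=n_units if n_units is not None else trace.unit_rates.shape[0],
        stable=stable, plateau_rate=last, drift_metric=drift)


def sweep_nssu_counts(counts: Sequence[int],
                      protocol: Optional[StimulusProtocol] = None,
                      criterion: StabilityCriterion = StabilityCriterion(),
                      p: Optional[MeanFieldParams] = None,
                      nr: Optional[NakaRushtonParams] = None,
                      dt: float = DEFAULT_DT,
                      stimulate: str = "basic",
                      ) -> Tuple[List[StabilityReport], Optional[int]]:
    """Run the storage protocol for each unit count and classify stability.

    Returns the per-count reports and the minimal stable count (``None``
    when no count in the sweep satisfies the criterion).
    """
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be a non-empty list")
    protocol = protocol or default_storage_protocol()
    reports = []
    for n in counts:
        system = build_set(SetConfig(n_units=n, stimulate=stimulate), p, nr)
        trace = simulate_set(system, protocol, dt)
        reports.append(classify_stability(trace, criterion, n_units=n))
    stable_counts = [r.n_units for r in reports if r.stable]
    minimal = min(stable_counts) if stable_counts else None
    return reports, minimal


def perturb_and_measure(system: SetSystem, spec: PerturbationSpec,
                        protocol: Optional[StimulusProtocol] = None,
                        dt: float = DEFAULT_DT,
                        criterion: StabilityCriterion = StabilityCriterion(),
                        ) -> PerturbationResult:
    """Measure robustness to a transient synaptic-weight disturbance.

    The perturbed run is compared pointwise with an unperturbed reference.
    The metric is the maximum absolute deviation of the mean rate after
    perturbation onset; recovery holds when the deviation over the final
    assessment window falls back inside a band of ``drift_tol`` times the
    pre-perturbation mean rate.
    """
    protocol = protocol or default_storage_protocol()
    horizon = protocol.total_duration
    stim_end = max(onset + dur for onset, dur, _ in protocol.pulses)
    window = spec.window_fraction * horizon
    if spec.onset < stim_end:
        raise ValueError(
            f"perturbation onset {spec.onset} ms precedes stimulus offset "
            f"{stim_end} ms; storage must complete first")
    if spec.onset + window > horizon:
        raise ValueError("perturbation window extends past the simulation horizon")

    key = spec.target[2:]  # "J_EE" -> "EE"
    ref = _integrate(system, protocol, dt)
    pert = _integrate(system, protocol, dt,
                      perturb=(key, spec.magnitude, spec.onset, spec.onset + window))
    start = int(round(spec.onset / dt))
    deviation = np.abs(pert.mean_rate - ref.mean_rate)[start:]
    times = ref.times[start:]
    metric = float(deviation.max()) if len(deviation) else 0.0

    pre_window = max(1, int(round(criterion.window_fraction * len(ref.mean_rate))))
    pre_plateau = float(ref.mean_rate[max(0, start - pre_window):start].mean())
    band = criterion.drift_tol * max(pre_plateau, criterion.floor * 1e-3)
    tail = deviation[-max(1, int(round(criterion.window_fraction * len(deviation)))):]
    recovery = bool(tail.max() <= band)
    return PerturbationResult(metric=metric, recovery=recovery,
                              deviation=deviation, times=times)
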