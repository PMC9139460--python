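"""Behavioral replication studies on top of the storage network.

Five classic working-memory paradigms are reproduced at trend level:

* **A — delayed response**: one cue is stored and probed after a variable
  delay; recall probability declines with delay and reaches zero once the
  stored rate crosses the forgetting threshold.
* **B/C — sequence association and updating**: item identity and item
  position are carried by separate feature channels (one SDN per channel)
  sharing an item id; recall of an item requires both channels, and for
  sequences longer than the four-item capacity only the most recent items
  survive (the update path), so e.g. only the last three letters of a long
  sequence can be reproduced in order.
* **D — feature binding**: change detection from colour, shape, either, or
  their conjunction; the conjunction readout is the product of the two
  channel probabilities, so binding performance never exceeds the
  single-feature conditions.
* **E — serial position with rehearsal**: a word list longer than capacity
  yields a pure recency curve under passive decay; rehearsing the earliest
  held word during the inter-word gaps protects it from eviction and adds a
  primacy component.  With a fixed four-item store this protection
  necessarily displaces a middle item — the classic primacy/recency
  trade-off, not a defect.

Recall readout: stored rates map to recall probability through a logistic
in the rate normalized by the storage plateau, clamped to zero below the
forgetting threshold.  Any monotone link preserves the trends asserted
here; the logistic is a convenient smooth choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import sdn as sdn_mod
from .sdn import SdnParams, SdnState, build_sdn, advance_time, present_stimulus


@dataclass(frozen=True)
class RecallReadout:
    """Monotone map from a SET's current rate to recall probability.

    ``p = 1 / (1 + exp(-k (r / plateau - c)))`` for rates above the
    forgetting threshold, 0 at or below it.
    """

    k: float = 10.0
    c: float = 0.5

    def __call__(self, rate: float, plateau: float, threshold: float) -> float:
        if rate <= threshold or plateau <= 0:
            return 0.0
        return 1.0 / (1.0 + math.exp(-self.k * (rate / plateau - self.c)))


@dataclass
class ExperimentResult:
    """Outcome of one replication study: the independent-variable grid, a
    recall probability per grid point, and the full SDN event log."""

    experiment_id: str
    grid: List
    probabilities: List[float]
    events: List[dict]
    extras: Dict = field(default_factory=dict)


def _recall_p(state: SdnState, feature_id: str, readout: RecallReadout) -> float:
    p = state.params
    return readout(sdn_mod.feature_rate(state, feature_id),
                   p.plateau_rate, p.forget_threshold)


def run_delay_experiment(delays: Sequence[float],
                         params: Optional[SdnParams] = None,
                         readout: RecallReadout = RecallReadout(),
                         ) -> ExperimentResult:
    """Store one cue and probe recall after each delay (ms).

    ``delays`` must be sorted ascending and nonnegative.  Also reports the
    spread of SET rates (stored vs. empty components) per delay, which is
    widest at response onset and narrows as the memory fades.
    """
    delays = list(delays)
    if any(d < 0 for d in delays):
        raise ValueError("delays must be >= 0")
    if delays != sorted(delays):
        raise ValueError("delays must be sorted ascending")
    params = params or SdnParams()
    probs, spreads, events = [], [], []
    for delay in delays:
        state = build_sdn(params)
        state, _ = present_stimulus(state, "cue")
        if delay > 0:
            state = advance_time(state, delay)
        probs.append(_recall_p(state, "cue", readout))
        rates = [item.stored_rate if item else 0.0 for item in state.sets.values()]
        spreads.append(max(rates) - min(rates))
        events = state.events
    return ExperimentResult("A", delays, probs, events,
                            extras={"rate_spread": spreads})


def _present_paired(channels: Dict[str, SdnState], item: int,
                    features: Dict[str, str]) -> Dict[str, SdnState]:
    out = {}
    for channel, state in channels.items():
        out[channel], _ = present_stimulus(state, features[channel])
    return out


def _advance_all(channels: Dict[str, SdnState], dt: float) -> Dict[str, SdnState]:
    return {ch: advance_time(st, dt) for ch, st in channels.items()}


def run_association_experiment(n_items: int, hold_time: float = 0.0,
                               item_interval: float = 1000.0,
                               params: Optional[SdnParams] = None,
                               readout: RecallReadout = RecallReadout(),
                               ) -> ExperimentResult:
    """Sequence memory with identity-position binding and updating.

    Item ``i`` is presented as paired features on an identity channel and a
    position channel (one SDN each, shared item index).  Presentations are
    ``item_interval`` ms apart (200 ms display + 800 ms blank by default);
    the probe follows the last item after ``hold_time`` ms.  An item is
    recallable only when both of its channels are above threshold, so for
    sequences longer than capacity only the most recent items survive.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    params = params or SdnParams()
    channels = {"identity": build_sdn(params), "position": build_sdn(params)}
    for i in range(1, n_items + 1):
        channels = _present_paired(channels, i, {
            "identity": f"item{i}", "position": f"pos{i}"})
        if i < n_items:
            channels = _advance_all(channels, item_interval)
    if hold_time > 0:
        channels = _advance_all(channels, hold_time)
    grid = list(range(1, n_items + 1))
    probs = []
    for i in grid:
        p_id = _recall_p(channels["identity"], f"item{i}", readout)
        p_pos = _recall_p(channels["position"], f"pos{i}", readout)
        probs.append(p_id * p_pos)
    order = [ev["feature_id"] for ev in channels["identity"].events
             if ev["event"] == "stored"]
    events = channels["identity"].events + channels["position"].events
    return ExperimentResult("B", grid, probs, events,
                            extras={"presentation_order": order})


PROBE_TYPES = ("color", "shape", "either", "binding")


def run_binding_experiment(probe_type: str, n_items: int = 3,
                           probe_delay: float = 906.0,
                           item_interval: float = 147.0,
                           params: Optional[SdnParams] = None,
                           readout: RecallReadout = RecallReadout(),
                           ) -> ExperimentResult:
    """Change detection over colour, shape, either feature, or their binding.

    Items carry a colour feature and a shape feature on separate channels.
    Detection probability per item: the relevant channel's recall for the
    single-feature probes, their mean when either feature may change, and
    their product for a binding change (both features of both items must be
    retrieved to notice a swap) — hence binding trails the single-feature
    conditions.  A zero-change probe is always answered "same" (the model
    has no false-alarm mechanism).
    """
    if probe_type not in PROBE_TYPES:
        raise ValueError(f"probe_type must be one of {PROBE_TYPES}, got {probe_type!r}")
    params = params or SdnParams()
    channels = {"color": build_sdn(params), "shape": build_sdn(params)}
    for i in range(1, n_items + 1):
        channels = _present_paired(channels, i, {
            "color": f"color{i}", "shape": f"shape{i}"})
        if i < n_items:
            channels = _advance_all(channels, item_interval)
    if probe_delay > 0:
        channels = _advance_all(channels, probe_delay)
    grid = list(range(1, n_items + 1))
    probs = []
    for i in grid:
        p_c = _recall_p(channels["color"], f"color{i}", readout)
        p_s = _recall_p(channels["shape"], f"shape{i}", readout)
        if probe_type == "color":
            probs.append(p_c)
        elif probe_type == "shape":
            probs.append(p_s)
        elif probe_type == "either":
            probs.append(0.5 * p_c + 0.5 * p_s)
        else:
            probs.append(p_c * p_s)
    events = channels["color"].events + channels["shape"].events
    return ExperimentResult("D", grid, probs, events,
                            extras={"probe_type": probe_type,
                                    "p_same_no_change": 1.0})


def run_serial_position_experiment(n_words: int = 8, rehearsal: bool = False,
                                   word_onset_interval: float = 2000.0,
                                   word_duration: float = 1000.0,
                                   params: Optional[SdnParams] = None,
                                   readout: RecallReadout = RecallReadout(),
                                   ) -> ExperimentResult:
    """Serial-position curve for a word list probed immediately after study.

    Words appear at ``word_onset_interval`` spacings (1 s display within a
    2 s cycle by default).  With ``rehearsal`` the earliest still-held word
    is covertly re-presented during each inter-word gap, refreshing its SET
    and protecting it from first-in-first-out eviction (primacy); without
    rehearsal the curve is pure recency.
    """
    if n_words < 2:
        raise ValueError("n_words must be >= 2")
    params = params or SdnParams()
    state = build_sdn(params)
    gap = word_onset_interval - word_duration
    if gap <= 0:
        raise ValueError("word_onset_interval must exceed word_duration")
    for i in range(1, n_words + 1):
        state, _ = present_stimulus(state, f"word{i}")
        if i < n_words:
            state = advance_time(state, word_duration)
            if rehearsal:
                held = state.held_items()
                if held:
                    earliest = min(held, key=lambda it: it.store_order)
                    state, _ = present_stimulus(state, earliest.feature_id)
            state = advance_time(state, gap)
    grid = list(range(1, n_words + 1))
    probs = [_recall_p(state, f"word{i}", readout) for i in grid]
    return ExperimentResult("E", grid, probs, state.events,
                            extras={"rehearsal": rehearsal})
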