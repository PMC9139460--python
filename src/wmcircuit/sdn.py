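"""Storage distribution network (SDN): routing, storing, updating, forgetting.

The SDN is a selector circuit of pyramidal nodes (``E00, E11, ..., E45``)
and interneurons (``I11, ..., I41``) that distributes incoming stimuli over
four storage sub-networks (``set11 .. set41``).  Its wiring implements three
rules:

* **Winner-take-all** — when a stimulus enters at ``E00`` every branch head
  receives it, but the first open branch activates its interneuron chain
  (``E11 -> I11`` etc.), which inhibits the sibling branches; exactly one
  SET-gating pyramidal node fires per stimulus.
* **Branch locking** — while a SET holds an item, the interneuron fed by
  its gate (``I12, I22, I32, I41``) stays active and keeps that branch
  closed, so successive stimuli fill ``set11, set21, set31, set41`` in
  order.  ``I12/I22/I32`` also silence the earlier-stage interneurons so a
  later signal can travel past previously used branches.
* **FIFO forgetting** — stored items decay under hybrid-feedback dynamics
  with slightly sub-critical positive feedback, so under pure decay the
  earliest item always has the lowest rate.  When all four SETs are
  occupied, the next stimulus overwrites the SET with the lowest current
  rate; items whose rate crosses the forgetting threshold are dropped and
  their SET freed.

Two node abstractions are available.  In the default **logic mode** nodes
are binary threshold units obeying the causal rules exactly.  In **rate
mode** every node carries a firing rate through the Naka-Rushton transfer
and the same routing emerges from the weight configuration, which must
satisfy the dominance constraints (inhibition stronger than the summed
excitatory drive wherever the wiring requires a node to be silenced).

Stored-item decay is the closed-form solution of the hybrid feedback unit,
``r(t) = r0 * exp(-(1 - w_pos) * t / (tau + w_der))``, evaluated exactly by
:func:`advance_time` rather than stepped numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .mean_field import NakaRushtonParams, naka_rushton
from .rate_models import FeedbackParams

# --------------------------------------------------------------------------
# Topology (branch order encodes routing priority)

SET_IDS = ("set11", "set21", "set31", "set41")

BRANCHES: Dict[int, Tuple[str, ...]] = {
    1: ("E11", "E12"),
    2: ("E22", "E23"),
    3: ("E32", "E33", "E34"),
    4: ("E42", "E43", "E44", "E45"),
}

#: SET-gating pyramidal node of each branch.
GATES: Dict[str, str] = {"E12": "set11", "E23": "set21", "E34": "set31", "E45": "set41"}

E_NODES = ("E00", "E11", "E12", "E22", "E23", "E32", "E33", "E34",
           "E42", "E43", "E44", "E45")
I_NODES = ("I11", "I12", "I21", "I22", "I31", "I32", "I41")

#: Excitatory drive of interneurons by pyramidal nodes.
E_TO_I: Dict[str, str] = {
    "E11": "I11", "E12": "I12", "E22": "I21", "E23": "I22",
    "E33": "I31", "E34": "I32", "E45": "I41",
}

#: Inhibitory edges.  I32 additionally silences the gate nodes E12/E23/E34
#: (the fourth-period wiring implied by the third-stage stage having "the
#: same effect" as the earlier ones), without which the fourth stimulus
#: would re-enter branch 1.
I_TARGETS: Dict[str, Tuple[str, ...]] = {
    "I11": ("E22", "E32", "E42"),
    "I12": ("I11", "E12"),
    "I21": ("E33", "E43"),
    "I22": ("I11", "I21", "E12", "E23"),
    "I31": ("E44",),
    "I32": ("I11", "I21", "I31", "E12", "E23", "E34"),
    "I41": ("I21", "I31", "E23", "E34", "E45"),
}

#: Interneuron kept active while a SET holds an item (branch lock).
OCCUPANCY_LOCK: Dict[str, str] = {
    "set11": "I12", "set21": "I22", "set31": "I32", "set41": "I41",
}

BRANCH_OF_SET: Dict[str, int] = {"set11": 1, "set21": 2, "set31": 3, "set41": 4}


def excitatory_edges() -> List[Tuple[str, str]]:
    edges = [("E00", chain[0]) for chain in BRANCHES.values()]
    for chain in BRANCHES.values():
        edges += list(zip(chain[:-1], chain[1:]))
    edges += [(e, i) for e, i in E_TO_I.items()]
    edges += [(gate, set_id) for gate, set_id in GATES.items()]
    return edges


def inhibitory_edges() -> List[Tuple[str, str]]:
    return [(i, t) for i, targets in I_TARGETS.items() for t in targets]


# --------------------------------------------------------------------------
# Configuration and state

@dataclass(frozen=True)
class SdnParams:
    """SDN build parameters.

    ``plateau_rate`` is the firing rate a SET settles at when an item is
    stored (rate units); ``forget_fraction`` sets the total-forgetting
    threshold as a fraction of that plateau; ``decay`` are the hybrid-unit
    parameters governing the slow decline of stored activity (slightly
    sub-critical positive feedback by default, giving an effective decay
    time constant of 20 s).
    """

    mode: str = "logic"
    excitatory_weight: float = 1.0
    inhibitory_weight: float = 2.0
    weight_overrides: Dict[str, float] = field(default_factory=dict)
    plateau_rate: float = 50.0
    forget_fraction: float = 0.1
    decay: FeedbackParams = field(
        default_factory=lambda: FeedbackParams(tau=20.0, w_pos=0.999, w_der=0.0))
    activation_threshold: float = 0.5
    rate_input_scale: float = 150.0
    nr: NakaRushtonParams = field(default_factory=NakaRushtonParams)

    def __post_init__(self) -> None:
        if self.mode not in ("logic", "rate"):
            raise ValueError("mode must be 'logic' or 'rate'")
        if not (0 < self.forget_fraction < 1):
            raise ValueError("forget_fraction must lie in (0, 1)")
        if self.plateau_rate <= 0:
            raise ValueError("plateau_rate must be > 0")
        if self.decay.w_pos >= 1.0:
            raise ValueError("decay w_pos must be < 1 so stored rates decline")

    def edge_weight(self, src: str, dst: str) -> float:
        key = f"{src}->{dst}"
        if key in self.weight_overrides:
            return self.weight_overrides[key]
        return self.inhibitory_weight if src.startswith("I") else self.excitatory_weight

    @property
    def forget_threshold(self) -> float:
        return self.forget_fraction * self.plateau_rate

    @property
    def decay_time_constant(self) -> float:
        """Effective decay time constant (tau + w_der) / (1 - w_pos), ms."""
        return (self.decay.tau + self.decay.w_der) / (1.0 - self.decay.w_pos)


@dataclass
class MemoryItem:
    """One stored feature: its SET, current rate and storage bookkeeping."""

    feature_id: str
    stored_rate: float
    store_time: float
    set_id: str
    store_order: int = 0


@dataclass
class SdnState:
    """Full SDN state: node activations, per-SET occupancy and clock."""

    params: SdnParams
    node_states: Dict[str, float]
    sets: Dict[str, Optional[MemoryItem]]
    clock: float = 0.0
    events: List[dict] = field(default_factory=list)
    _store_counter: int = 0

    def copy(self) -> "SdnState":
        return SdnState(
            params=self.params,
            node_states=dict(self.node_states),
            sets={k: (replace(v) if v is not None else None)
                  for k, v in self.sets.items()},
            clock=self.clock,
            events=list(self.events),
            _store_counter=self._store_counter,
        )

    def held_items(self) -> List[MemoryItem]:
        return [v for v in self.sets.values() if v is not None]

    def held_count(self) -> int:
        return len(self.held_items())

    def free_sets(self) -> List[str]:
        return [s for s in SET_IDS if self.sets[s] is None]

    def find_feature(self, feature_id: str) -> Optional[MemoryItem]:
        for item in self.held_items():
            if item.feature_id == feature_id:
                return item
        return None


# --------------------------------------------------------------------------
# Construction and validation

def validate_dominance(params: SdnParams) -> None:
    """Check that every inhibitory edge can actually silence its target.

    The causal wiring requires inhibition to dominate wherever a node is
    meant to be suppressed, so each inhibitory weight must exceed the summed
    excitatory weight into its target node.  Raises ``ValueError`` naming
    the first violated constraint.
    """
    exc_in: Dict[str, float] = {}
    for src, dst in excitatory_edges():
        exc_in[dst] = exc_in.get(dst, 0.0) + params.edge_weight(src, dst)
    for i_node, dst in inhibitory_edges():
        w = params.edge_weight(i_node, dst)
        drive = exc_in.get(dst, 0.0)
        if w <= drive:
            raise ValueError(
                f"dominance violated for edge {i_node}->{dst}: inhibitory "
                f"weight {w} must exceed the excitatory drive {drive} into {dst}")


def build_sdn(params: Optional[SdnParams] = None) -> SdnState:
    """Build an SDN at rest: all nodes inactive, all four SETs free."""
    params = params or SdnParams()
    validate_dominance(params)
    nodes = {n: 0.0 for n in E_NODES + I_NODES}
    return SdnState(params=params, node_states=nodes,
                    sets={s: None for s in SET_IDS})


# --------------------------------------------------------------------------
# Routing

def _effective_locks(state: SdnState) -> set:
    """Interneurons held active by occupied SETs, minus those silenced by a
    stronger lock (e.g. I32 silences I31 while set31 is occupied)."""
    locks = {OCCUPANCY_LOCK[s] for s in SET_IDS if state.sets[s] is not None}
    return {i for i in locks
            if not any(i in I_TARGETS[j] for j in locks if j != i)}


def _propagate_logic(state: SdnState) -> Tuple[Dict[str, float], Optional[str]]:
    """Walk the branches in priority order with binary threshold nodes.

    Returns the node activations of the episode and the selected SET (the
    unique gate that fired), or ``None`` when every branch is locked.
    """
    active: Dict[str, float] = {n: 0.0 for n in E_NODES + I_NODES}
    inhibitors: set = set(_effective_locks(state))
    for i in inhibitors:
        active[i] = 1.0
    active["E00"] = 1.0
    winner: Optional[str] = None

    def blocked(node: str) -> bool:
        return any(node in I_TARGETS[i] for i in inhibitors)

    def fire_i(e_node: str) -> None:
        i_node = E_TO_I.get(e_node)
        if i_node is not None and not blocked(i_node):
            active[i_node] = 1.0
            inhibitors.add(i_node)

    for branch in sorted(BRANCHES):
        for depth, node in enumerate(BRANCHES[branch]):
            driver_on = depth == 0 or active[BRANCHES[branch][depth - 1]] > 0
            if not driver_on or blocked(node):
                break
            active[node] = 1.0
            fire_i(node)
            if node in GATES and winner is None:
                winner = GATES[node]
    return active, winner


def _propagate_rate(state: SdnState, amplitude: float
                    ) -> Tuple[Dict[str, float], Optional[str]]:
    """Rate-mode routing: the same causal priority walk as logic mode, but
    each node carries a Naka-Rushton firing rate computed from its weighted
    input, and a node fires when its rate crosses half-maximum.  With
    dominance-satisfying weights the winner coincides with logic mode;
    weaker weights change who gets silenced, which is the point of exposing
    the mode."""
    p = state.params

    def rate_of(u: float) -> float:
        return float(naka_rushton(u * p.rate_input_scale, p.nr)) / p.nr.m_max

    a: Dict[str, float] = {n: 0.0 for n in E_NODES + I_NODES}
    inhibitors = set(_effective_locks(state))
    for i in inhibitors:
        a[i] = 1.0
    a["E00"] = rate_of(amplitude)
    winner: Optional[str] = None

    def input_to(node: str, exc_sources: List[str]) -> float:
        u = sum(p.edge_weight(s, node) * a[s] for s in exc_sources)
        u -= sum(p.edge_weight(i, node) * a[i]
                 for i in inhibitors if node in I_TARGETS[i])
        return u

    for branch in sorted(BRANCHES):
        chain = BRANCHES[branch]
        for depth, node in enumerate(chain):
            parent = "E00" if depth == 0 else chain[depth - 1]
            a[node] = rate_of(input_to(node, [parent]))
            if a[node] <= 0.5:
                break
            i_node = E_TO_I.get(node)
            if i_node is not None and i_node not in inhibitors:
                a[i_node] = rate_of(input_to(i_node, [node]))
                if a[i_node] > 0.5:
                    inhibitors.add(i_node)
            if node in GATES and winner is None:
                winner = GATES[node]
    rates = {n: v * p.nr.m_max for n, v in a.items()}
    return rates, winner


def route_stimulus(state: SdnState, feature_id: str, amplitude: float
                   ) -> Tuple[SdnState, Optional[str]]:
    """Route one stimulus through the selector circuit.

    Selection rules, in order: a feature already held re-selects the SET
    that stores it (memory retelling); otherwise the circuit's first open
    branch wins; when every SET is occupied the branch of the
    lowest-rate SET reopens (the FIFO update path).  Sub-threshold
    amplitudes do not route: the state is unchanged apart from a warning
    event and ``None`` is returned.
    """
    new = state.copy()
    if amplitude < state.params.activation_threshold:
        new.events.append({"t": new.clock, "event": "subthreshold",
                           "feature_id": feature_id, "set_id": None,
                           "rate": 0.0})
        return new, None

    held = state.find_feature(feature_id)
    if held is not None:
        selected = held.set_id
        new.node_states = _branch_activity(selected)
        return new, selected

    if state.params.mode == "rate":
        nodes, winner = _propagate_rate(state, amplitude)
    else:
        nodes, winner = _propagate_logic(state)

    if winner is None:
        free = state.free_sets()
        if free:
            # A branch can stay closed by a later stage's lock even though
            # its SET was freed by forgetting; reopen the earliest free one.
            winner = free[0]
            nodes = _branch_activity(winner)
        else:
            items = state.held_items()
            weakest = min(items, key=lambda it: (it.stored_rate, it.store_order))
            winner = weakest.set_id
            nodes = _branch_activity(winner)
    new.node_states = nodes
    return new, winner


def _branch_activity(set_id: str) -> Dict[str, float]:
    """Node activations for a directly re-excited branch (refresh/reopen)."""
    active = {n: 0.0 for n in E_NODES + I_NODES}
    active["E00"] = 1.0
    chain = BRANCHES[BRANCH_OF_SET[set_id]]
    for node in chain:
        active[node] = 1.0
    i_node = E_TO_I.get(chain[-1])
    if i_node is not None:
        active[i_node] = 1.0
    return active


# --------------------------------------------------------------------------
# Storage, update, decay

def store_or_update(state: SdnState, set_id: str, feature_id: str) -> SdnState:
    """Store ``feature_id`` in ``set_id``: fill a free SET, refresh the SET
    if it already holds this feature, or atomically evict and overwrite the
    occupant otherwise.  The evicted item is reported in the event log."""
    if set_id not in SET_IDS:
        raise ValueError(f"unknown SET handle {set_id!r}")
    new = state.copy()
    params = state.params
    occupant = new.sets[set_id]
    if occupant is not None and occupant.feature_id == feature_id:
        occupant.stored_rate = params.plateau_rate
        new.events.append({"t": new.clock, "event": "refreshed",
                           "feature_id": feature_id, "set_id": set_id,
                           "rate": occupant.stored_rate})
        return new
    if occupant is not None:
        new.events.append({"t": new.clock, "event": "evicted",
                           "feature_id": occupant.feature_id, "set_id": set_id,
                           "rate": occupant.stored_rate})
    new._store_counter += 1
    new.sets[set_id] = MemoryItem(
        feature_id=feature_id, stored_rate=params.plateau_rate,
        store_time=new.clock, set_id=set_id, store_order=new._store_counter)
    new.events.append({"t": new.clock, "event": "stored",
                       "feature_id": feature_id, "set_id": set_id,
                       "rate": params.plateau_rate})
    return new


def present_stimulus(state: SdnState, feature_id: str, amplitude: float = 1.0
                     ) -> Tuple[SdnState, Optional[str]]:
    """Route a stimulus and store/refresh it: the full per-item pathway."""
    state, set_id = route_stimulus(state, feature_id, amplitude)
    if set_id is None:
        return state, None
    return store_or_update(state, set_id, feature_id), set_id


def advance_time(state: SdnState, dt_total: float) -> SdnState:
    """Advance the clock by ``dt_total`` ms, decaying every stored item
    along the closed-form hybrid-unit solution.  Items crossing the
    forgetting threshold are dropped and their SET freed, with the crossing
    time recorded in the event log."""
    if dt_total <= 0:
        raise ValueError("dt_total must be > 0")
    new = state.copy()
    params = state.params
    tau_eff = params.decay_time_constant
    threshold = params.forget_threshold
    factor = math.exp(-dt_total / tau_eff)
    forgotten = []
    for set_id in SET_IDS:
        item = new.sets[set_id]
        if item is None:
            continue
        decayed = item.stored_rate * factor
        if decayed < threshold:
            t_cross = new.clock + tau_eff * math.log(item.stored_rate / threshold)
            forgotten.append((t_cross, set_id, item))
            new.sets[set_id] = None
        else:
            item.stored_rate = decayed
    for t_cross, set_id, item in sorted(forgotten):
        new.events.append({"t": t_cross, "event": "forgotten",
                           "feature_id": item.feature_id, "set_id": set_id,
                           "rate": threshold})
    new.clock += dt_total
    return new


def feature_rate(state: SdnState, feature_id: str) -> float:
    """Current rate of the SET holding ``feature_id``; 0 when not held."""
    item = state.find_feature(feature_id)
    return item.stored_rate if item is not None else 0.0
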