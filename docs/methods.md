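# Methods

This note documents the models implemented in `wmcircuit`, the choices made
where the circuit description leaves the design open, and what the
synthetic protocols can and cannot show.

## Single-unit feedback models (`rate_models`)

A memory unit must counteract the leak of its membrane current to hold a
rate after the input goes away. Three linear units capture the options:

* Positive feedback: `τ dr/dt = −(1 − W_pos) r + I(t)`. The printed form of
  this equation is ambiguous about the grouping of the leak and feedback
  terms; we use the grouping under which `W_pos = 1` is the balanced point,
  `W_pos < 1` decays and `W_pos > 1` grows — the behaviour the model is
  defined by.
* Negative-derivative feedback demo: the pair `τ drE/dt = −W_pos rE + I(t)`,
  `τ drI/dt = −W_der rI + I(t)` with the *literal* decay coefficients; the
  difference `rE − rI` shows the corrective transient produced by fast
  inhibitory versus slow excitatory kinetics.
* Hybrid (HPNF): `τ dr/dt = −r + W_pos r − W_der dr/dt + I(t)`. The
  implicit `dr/dt` on the right is resolved algebraically to
  `(τ + W_der) dr/dt = −(1 − W_pos) r + I(t)` before integration. After the
  rearrangement `W_der` adds to `τ` and therefore acts as a time-like
  coefficient (ms), although it originates as a synaptic strength; the
  effective relaxation time is `(τ + W_der)/(1 − W_pos)`.

Integration is forward Euler at `dt = 0.1 ms` (precondition `dt ≤ τ/10`),
with a fixed-step RK4 scheme available as a reference; because the drive is
piecewise constant, RK4 is essentially exact for these linear systems and
serves as the oracle in the tests, alongside closed-form exponentials and
an adaptive `solve_ivp` cross-check. Initial conditions default to rest
(0) and are overridable. The units are left unrectified: rectification
enters only through the population transfer function. Optional input noise
is additive Gaussian per time step, seeded.

## E/I population model (`mean_field`)

Each self-sustaining unit is a pyramidal/interneuron population pair with
rates `r_E, r_I` and synaptic activations `s_EE, s_EI, s_IE, s_II`:

    τ_E dr_E/dt = −r_E + f(J_EE s_EE − J_EI s_EI + J_EO i(t))
    τ_I dr_I/dt = −r_I + f(J_IE s_IE − J_II s_II)
    τ_ij ds_ij/dt = −s_ij + r_j

`s_ij` is read as the synapse onto element `i` from element `j`, relaxing
toward the presynaptic rate `r_j` — the only reading consistent with the
relaxation equation. Defaults: `τ_E = 20`, `τ_I = 10`, `τ_EE = 100`,
`τ_EI = 25`, `τ_IE = τ_II = 10` ms; intra-unit `J_EE/J_EI/J_IE/J_II =
300/450/900/900`, inter-unit `150/300/600/600`; `J_EO ∈ [0, 6000]`, default
3000 (mid-range; the sources state only the range). The slow E→E kinetics
against fast inhibition implement negative-derivative feedback at the
population level.

The transfer function is the thresholded Naka–Rushton form

    f(x) = M (x − x_θ)² / (x_0² + (x − x_θ)²) · h(x − x_θ)

with `M = 100`, `x_θ = 30`, `x_0 = 30`. The printed denominator is
typographically garbled; this is the standard form under which `x_θ` is an
input threshold and `x_0` a half-activation parameter
(`f(x_θ + x_0) = M/2`). The Heaviside convention is `h(0) = 0`, so
`f(x_θ) = 0` exactly. `f` bounds rates to `[0, M]` at every step.

## SET bank (`set_network`)

A SET is `n` units (NSSUs) coupled all-to-all: connections within a unit
use the intra-unit weights, connections between any two units the
inter-unit weights, giving `6n` state variables. The wiring diagram of the
source circuit shows parallel units but not the graph; all-to-all is the
simplest symmetric choice consistent with "backup" units mirroring the
basic one. The external stimulus enters through the basic unit (the fifth,
or the last for banks smaller than five) by default; direct drive of all
units is available behind a flag. The standard storage protocol is a
200 ms pulse at the start of a 2000 ms horizon at `dt = 0.1 ms`.

Stability criterion (the source states none): a trace is *stable* when the
mean rate over the final 10 % of the run differs from the mean over the
preceding 10 % by less than 2 % (relative) **and** exceeds an activity
floor of 1.0 rate units. Both tolerances are configurable.

### Why the bank-size sweep finds no stable count at the printed weights

At any jointly active state the summed recurrent drive onto an excitatory
population is `A(n)·r − B(n)·r` with `A(n) = 300 + 150(n−1)` and
`B(n) = 450 + 300(n−1)`, i.e. a net `−150 n · r`: inhibition outweighs
excitation for *every* bank size, and the inter-unit values (exactly half
the intra-unit ones) preserve the imbalance, while the inhibitory
population's own drive has `J_IE = J_II` exactly. The only fixed point of
the bank is therefore the resting state, and every post-stimulus
trajectory relaxes back to rest on a timescale set by the synaptic
filters — which we confirmed numerically for `n = 2..12` across stimulus
amplitudes, both stimulation modes and horizons up to 4 s, and under the
alternative index convention for `J_ij` (which yields the same `−150 n`
slope). Seeded per-step input noise can sustain activity, but then the
windowed drift statistic is dominated by the noise realization and the
minimal stable count is not reproducible. The sweep machinery is
implemented and tested in full; under these study conditions it honestly
reports that no count in 2–12 passes the plateau criterion, rather than
reproducing the reported minimum of eight. The corresponding acceptance
test states the reported value and fails.

### Perturbation protocol

Robustness to a transient disturbance (e.g. +5 % of `J_EE` for 2 % of the
run, after storage) is measured against the *unperturbed reference
trajectory*: the metric is the maximum deviation of the mean rate after
perturbation onset, and recovery holds when the deviation re-enters a band
of 2 % of the pre-perturbation mean by the end of the run. Anchoring the
band to the reference trajectory rather than a constant plateau keeps the
measure meaningful for relaxing activity. Under this protocol the
eight-unit bank recovers from 5 % disturbances of each of the four weights,
and deviations shrink as units are added (redundant backups damp the
disturbance).

## Storage distribution network (`sdn`)

The SDN routes each stimulus to one of four SETs through a cascade of
pyramidal branches gated by interneurons. Nodes and inhibitory edges
follow the reported wiring, with three additions implied by the circuit's
own narrative (the third-stage lock interneuron `I32` must silence the
earlier gates `E12`, `E23` and its own gate `E34`, exactly as the earlier
stages do): without them the fourth stimulus would re-enter the first
branch.

* **Latch semantics** (not specified by the source): the interneuron fed by
  a gate (`I12, I22, I32, I41`) stays active while its SET holds an item,
  locking the branch; a latched interneuron is silenced by any latched
  interneuron that inhibits it (`I22 ⊣ I21`, `I32 ⊣ I31`, ...), which is
  what lets later signals travel past used branches. This reproduces the
  reported five-signal sequence, including the wrap of the fifth signal
  back to the first branch.
* **Logic mode** (default): nodes are binary threshold units walked in
  branch-priority, depth order with inhibition dominant — fast and exactly
  testable. **Rate mode**: the same causal walk with each node carrying a
  Naka–Rushton rate computed from its weighted input; a node fires above
  half-maximum. Build-time validation rejects any weight configuration in
  which an inhibitory edge cannot dominate the summed excitatory drive
  into its target, naming the violated edge.
* **Storage and decay**: a stored item pins its SET at a plateau rate
  (default 50, mid-range of `M`) and then decays along the closed-form
  hybrid-unit solution with slightly sub-critical feedback
  (`W_pos = 0.999`, `τ = 20 ms`, `W_der = 0` → effective time constant
  20 s); the forgetting threshold is 10 % of the plateau (total forgetting
  at `20 s · ln 10 ≈ 46 s`). The decay is evaluated analytically by
  `advance_time`, which also records threshold crossings at their exact
  times. Re-presenting a held feature re-selects its SET and restores the
  plateau (memory retelling).
* **Eviction**: with all SETs occupied, the SET with the lowest current
  rate is overwritten (ties broken toward the earlier item). Under pure
  decay with equal amplitudes this is exactly first-in-first-out; with
  rehearsal the refreshed item is protected and the next-weakest is
  evicted. A branch freed by forgetting can remain shadowed by a
  later-stage lock; routing then reopens the earliest free branch.

One SDN carries one feature channel; multi-feature objects use one SDN per
feature with a shared item id.

## Behavioral studies (`experiments`)

Recall probability is a logistic in the rate normalized by the storage
plateau, `p = 1/(1 + exp(−k(r/plateau − c)))` with `k = 10`, `c = 0.5`,
clamped to 0 at the forgetting threshold. The link is not specified by the
source; any monotone map preserves every trend asserted here. Timings
follow the replicated paradigms (200 ms character + 800 ms blank for letter
sequences; 1 s word in a 2 s cycle for the word list); the probe delays in
the delayed-response study are chosen relative to the model's 20 s decay
constant. Association and binding use paired channels with a conjunctive
readout (the product of channel probabilities), so binding performance
never exceeds single-feature performance. Rehearsal covertly re-presents
the earliest still-held word during each inter-word gap; with a hard
four-item capacity this necessarily displaces a middle item, so the
serial-position curve gains primacy at the rehearsed positions while a
middle position loses — rehearsal dominance holds at the rehearsed
positions, not pointwise across the list.

These protocols emulate idealized stimulus schedules: noiseless,
perfectly timed, with identical amplitudes. They do not model encoding
variability, retrieval noise, inter-item similarity or interference, so
passing trends here show the mechanism is sufficient for the qualitative
effects, not that it quantitatively fits behavioral data — the reported
behavioral figures print no numbers to fit.

## Numerical choices

* Forward Euler, `dt = 0.1 ms` everywhere by default; preconditions
  `dt ≤ τ/10` (single units) and `dt ≤ min(τ)/5` (populations).
* Exact analytic decay for stored SDN items (linear ODE; no accumulation
  of integration error over multi-minute spans).
* Divergent single-unit trajectories are flagged (`overflow=True`) rather
  than raised; population steps raise on the first non-finite state
  variable, naming it.
* Determinism: all randomness flows through seeded NumPy generators; equal
  seeds give bitwise-identical trajectories and byte-identical output
  files.

## Known limitations

* The bank-size result discussed above: the printed weight set does not
  admit a persistent plateau, so the "eight units suffice" claim is not
  recoverable from the stated equations alone.
* The SDN abstracts SET storage as plateau-plus-analytic-decay rather than
  embedding a live 48-variable bank per SET; this is what makes
  multi-minute forgetting protocols exact and fast, at the cost of not
  modelling storage transients inside the routing network.
* Rate mode chooses node gains (input scale 150) so that activation
  survives four-deep chains; it demonstrates the dominance logic with
  graded rates, not a fitted biophysical circuit.
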