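# Methods

## Model

One canonical microcircuit couples three neural masses — pyramidal cells
(Py), excitatory interneurons (EIN), inhibitory interneurons (IIN) —
through five synaptic channels. Each channel is an alpha-function
synapse: gain `H` (mV), time constant `τ` (s), critically damped
second-order dynamics `V̈ = (H/τ)u − (2/τ)V̇ − V/τ²` with `u` the total
afferent firing rate (s⁻¹). Channels 1, 2 and 4 are excitatory
(`Hₑ, τₑ`), channels 3 and 5 inhibitory (`Hᵢ, τᵢ`). Membrane potential
converts to firing rate through the logistic activation
`S(V) = 2e₀/(1+e^{r(v₀−V)})`, strictly increasing and bounded in
`(0, 2e₀)`.

Two dimensionless weights in `[0, 1]` interpolate the feedback topology.
`b₁` blends the excitatory loop from indirect (Py → EIN → Py, external
drive onto the EIN; `b₁ = 1`) to direct (Py self-feedback with gain
`N_PP`, drive onto the Py; `b₁ = 0`); intermediate values are legitimate
model states, and the resting `V_Py` varies continuously along the
interpolation (asserted by a test). `b₂` switches the recurrent IIN
self-inhibition: at `b₂ = 1` channel 5 receives no input and stays
identically zero; at `b₂ = 0` the IIN inhibits itself with gain `N_II`
(disinhibition).

Assumptions inherited from this model class: spatially lumped
populations (no conduction delays, no spatial extent), stationary
synaptic parameters (no plasticity), and rate coding through a static
sigmoid. All computation is carried out in physical units — mV, s, s⁻¹ —
with the millisecond time constants of the standard parameter set
converted to seconds at load. The state is serialized as
`(V₁…V₅, W₁…W₅)` with `W = V̇`.

### Parameters that matter

| symbol | meaning | default | unit |
|---|---|---|---|
| `Hₑ`, `Hᵢ` | excitatory / inhibitory synaptic gain (receptor density proxy); together they set the local excitation–inhibition balance | 3.25 / 22 | mV |
| `τₑ`, `τᵢ` | synaptic time constants | 0.010 / 0.020 | s |
| `N_EP` | EIN ← Py gain; `N_PE = 0.8 N_EP`, `N_IP = N_PI = 0.25 N_EP` | 135 | – |
| `N_PP` | direct Py self-feedback (active for `b₁ < 1`); fixed constant from the published two-population mapping, not re-derived here | 113.4 | – |
| `N_II` | IIN self-feedback (active for `b₂ < 1`) | 33.25 | – |
| `e₀, r, v₀` | activation: half-max rate, max slope, half-activation potential | 2.5 s⁻¹, 0.56 mV⁻¹, 6 mV | |
| `u_th` | firing threshold for behavior classification | 4 | mV |

The default balance places the circuit at the tip of the bistable wedge
in the `(Hₑ, Hᵢ)` plane: close enough to the fold structure that all
three response behaviors are reachable, which is why small balance
changes (e.g. `Hᵢ` 22 → 24 mV) have outsized functional consequences.

### Drives

`p_ext` is the architecture-routed external firing-rate drive (to the
EIN for `b₁ = 1`, to the Py for `b₁ = 0`). `p_iin` is an explicit
additive drive onto the IIN channel's input. The reset impulse used in
deactivation experiments is injected this way — through the existing
excitatory synapse onto the IIN rather than through a kernel of its own;
this was a genuinely open choice, made because it reuses the circuit's
own afferent machinery and adds no new parameters. Negative `p_ext`
occurs only in continuation (the fixed-point curve extends below zero);
simulation protocols use nonnegative drives.

## Numerical integration

Explicit two-stage Heun (Euler predictor, trapezoidal corrector), fixed
step `dt = 1 ms` by default. Drives are piecewise constant with
half-open pulse support `[onset, onset+duration)` on the step grid and
are evaluated once per step, held through both stages; when a drive is
noisy the Gaussian term is sampled once per step and frozen the same way
(a simple stochastic-Heun variant — the scheme choice was open and this
one keeps noisy and noise-free paths structurally identical).
State-dependent network coupling, by contrast, is re-evaluated at both
stages because it is part of the vector field. Equilibria of the ODE are
exact fixed points of the scheme, so long settled runs agree with the
root-found equilibria to ~1e−7 mV. A non-finite state aborts integration
with the offending batch row; the model itself cannot diverge under
bounded drives (the sigmoid bounds every channel input), which a sweep
test confirms at the default step. Convergence is second order (measured
slope ≥ 1.9 on a subthreshold transient). The sigmoid's exponent is
clamped at ±500 to avoid floating overflow; the clamp binds only beyond
|V| ≈ 900 mV and affects no reported quantity. Grid experiments
(fingerprints, maps) run all cells as one vectorized batch and record
only running window extrema of `V_Py`, which keeps a 21×21 fingerprint
(441 five-second runs) around two seconds and a full dynamic-function
map (~6 500 runs) well under a minute.

## Response classification

A run is 5 s: 1 s settling from the zero state, one rectangular pulse,
then free evolution. The maximum of `V_Py` is compared against
`u_th = 4 mV` in three windows — prestimulus (0.5–1 s), immediate
response (1.1–3.5 s), asymptotic (4–5 s) — giving an activation triple.
Uniform triples (never active, or active throughout) are
*nonresponsive*; otherwise asymptotic activity is *memory* and
immediate-only activity *transfer*. The maximum criterion deliberately
counts oscillation about the threshold as active, since such a
population drives its targets during part of each cycle. Triples with
prestimulus activity but non-uniform later windows cannot arise from
this protocol; they map to nonresponsive with a warning. An optional
oscillation flag (asymptotic peak-to-peak `V_Py` > 0.5 mV) marks
oscillatory variants instead of reproducing any finer taxonomy, whose
exact thresholds are not published. Default fingerprint resolution is
41×41 over 50–250 s⁻¹ × 0.5–1.5 s (the end-to-end checks use 21×21 to
keep runtimes modest); dynamic function maps summarize a 9×9 stimulus
grid per `(Hₑ, Hᵢ)` cell as the set of behaviors present plus the modal
behavior. The transfer/memory boundary is resolved by a dedicated
stimulus-offset scan (100 s⁻¹, 600–750 ms in 5 ms steps): whether the
circuit latches depends on the oscillation phase at switch-off, so
labels alternate along that scan; a 50 ms duration grid cannot resolve
these stripes.

Deactivation diagrams first latch the circuit with a memory-inducing
pulse (150 s⁻¹, 1.5 s), verify it is active, apply one IIN impulse at
4.5 s and judge the 7–8 s window of an 8 s run; they refuse to run for
parameterizations that are not bistable at zero drive, since "staying
latched" would be meaningless there.

## Equilibria and bifurcations

Two independent routes compute the fixed-point structure, and tests hold
them against each other:

* **Scalar reduction.** At equilibrium every channel reduces to
  `V = Hτu`, and all five potentials plus the drive are determined by
  `x = V_Py` alone: channels 4, 5, 3 follow from `x` (the V₅
  self-consistency for `b₂ < 1` is solved by monotone bisection — the
  naive fixed-point iteration is not a contraction at large `Hᵢ`), and
  the drive follows from channel 2 (closed form at `b₁ ∈ {0, 1}`,
  monotone bisection otherwise). Sweeping `x` densely gives the exact
  curve `p_ext(x)`; equilibria at given drive are its level-set
  crossings. For `b₁ = 1` the curve diverges logarithmically where `V₂`
  reaches the edge of the EIN sigmoid's range, and equilibria can sit
  arbitrarily close to these asymptotes, so the scan additionally probes
  them on a log-distance grid down to 1e−13 mV.
* **Newton / continuation.** Damped Newton on the five-dimensional
  steady-state residual from a deterministic grid of `V_Py` guesses
  (−10 to 16 mV) plus seeded random starts, de-duplicated; and
  pseudo-arclength continuation of `(V, p_ext)` with a bordered Newton
  corrector, adaptive step (drive weighted by 0.05 in the arclength
  metric so mV and s⁻¹ contribute comparably), and eigenvalues of the
  full 10-dimensional Jacobian at every accepted point.

Stability uses the analytic Jacobian (verified against finite
differences to 1e−6 relative); an eigenvalue real part counts as nonzero
above 1e−4 s⁻¹ (1e−6 after nondimensionalizing time by `τₑ`). Folds are
detected by a sign change of the tangent's drive component and refined
along the branch to 0.01 s⁻¹; their type is read off the spectrum at the
fold itself — apart from the vanishing eigenvalue, any remaining
unstable direction makes the fold saddle-saddle, otherwise saddle-node.
This local rule avoids probing branch segments at an arbitrary finite
offset, which matters because a detaching Hopf can sit arbitrarily close
to the fold. Hopf points are sign changes of the leading oscillatory
pair's real part; candidates whose refined point does not actually lie
on the imaginary axis (the discontinuous jump where a real pair merges
into a complex one near a fold) are rejected. Criticality is decided by
simulation probing ~2 s⁻¹ into the unstable side over a 20 s horizon —
growth rates next to the crossing are of order 0.1 s⁻¹, so shorter
probes cannot separate a bounded local cycle (supercritical) from escape
to a distant attractor (subcritical); normal-form coefficients for a
10-dimensional system were deliberately avoided as error prone.
Attractor counting (`bistability_check`) combines the stable-equilibrium
count with a limit-cycle probe started from the perturbed upper state;
limit-cycle continuation itself is out of scope.

The drive location of the Hopf is far more delicate than its state-space
location: the upper branch is steep there (`dp_ext/dV_Py` ≈ 175 s⁻¹ per
mV), so a discretized branch read off at finite resolution can misplace
the crossing by ~0.5 s⁻¹ while `V_Py` moves by thousandths of a mV. The
package therefore pins the Hopf by the exact eigenvalue crossing and
cross-checks it between the continuation and the scalar-reduction routes.

### Two-parameter loci

Fold loci at zero drive are traced through the `(Hₑ, Hᵢ)` plane by, for
each `Hᵢ`, bisecting `Hₑ` until the tracked fold's drive is zero. The
fold is followed between locus points by proximity in `V_Py` with a
warm-started `Hₑ` window, which keeps the trace on one fold sheet even
when the equilibrium curve has several extrema. Points carry the local
fold type, and a type change along the locus — the saddle-node →
saddle-saddle split where a subcritical Hopf branch detaches — is
bisected in `Hᵢ` to 0.02 mV. With the exact spectral typing rule the
flagged split is the fold–Hopf collision point; because the detached
Hopf separates from the fold only slowly (its drive offset grows from
~0.2 s⁻¹ to ~13 s⁻¹ over the next 1.5 mV of `Hᵢ` in the two-population
model), coarser typing conventions place the split visibly higher. The
default `(Hₑ, Hᵢ)` extents, 1–8 mV × 2–44 mV, were chosen to cover the
full qualitative repertoire around the defaults. The `N_II` sweep runs
the disinhibited model's branch per self-feedback level; at `N_II = 0`
it reproduces the plain two-population branch exactly, which is tested
event-for-event.

## Networks and the parsing demo

Nodes are full microcircuits with per-node parameters. Excitatory edges
add `gain · φ_P(source)` to the target's afferent route; inhibitory
edges drive the target's IIN — the same route as the reset impulse,
chosen because the model defines no other inhibitory entry point for
inter-areal signals. Contextual information is a noisy inhibitory offset
subtracted from the target's afferent input with a floor at zero
("degraded input" rather than extra IIN drive; both were defensible, the
subtraction reads most directly as input degradation). Context noise is
Gaussian, mean = offset, SD = 10 % of the offset, resampled every step;
no distribution is published, and 10 % keeps the signal reliably
inhibitory while exercising the seeded-noise path. A single-node network
with no edges reproduces the single-circuit integrator bit-for-bit
(tested), because both run the same stepping core.

The six-node demo represents each word of "I hit the thief with the
club" by one place-coded microcircuit grouped into syntactic modules.
Word onsets arrive every 1.2 s as 1 s, 120 s⁻¹ pulses — suprathreshold
and long enough to latch a circuit on its own, with onsets spaced so a
word's damped oscillation settles before the next arrives. Excitatory
edges along the expected word order (gain 5; 3 onto the shared object of
the preposition) pre-activate successors by a fraction of a millivolt —
a baseline shift toward the fold, measurable via `preactivation_level`
and monotone in the edge gain (tested) — without activating them. The
two 'with' nodes inhibit each other asymmetrically (20 verb→object, 4
object→verb): sustained IIN drive from an active competitor is the same
mechanism as the reset impulse, so the stronger direction deactivates
the loser. With contextual inhibition of the verb-modifier (offset
150 s⁻¹) its word input is degraded below the perception threshold and
the object-modifier reading wins; without context the verb-modifier wins
through its stronger inhibition. All gains are hand-tuned calibration
artifacts (no published values exist); `scripts/calibrate_demo.py`
sweeps the sensitive ones. Raising `Hᵢ` from 22 to 23–24 mV on all nodes
removes the single-circuit bistability, so no word can sustain its
activation and the parse degrades to a defective trace or total memory
loss; the outcome label is a pure function of the final activation bits
and the expected word set.

## What the experiments do and do not show

All inputs are self-generated: parameter sets, rectangular stimulus
protocols, gain grids and word schedules. They emulate idealized
stimulation experiments — noise-free rectangular drives, instantaneous
parameter switches, isolated circuits — not physiological input
statistics, measurement noise, delays or heterogeneous populations.
Passing tests therefore establish the internal dynamics of the model
(bifurcation structure, gating/memory repertoire, balance sensitivity,
network mechanism), not a fit to empirical recordings. The parsing demo
is a mechanistic proof of concept on one sentence with hand-calibrated
weights; its qualitative outcomes, not its weight values, are the
claims.

## Problem sizes and tolerances used by the test suite

Fingerprints 21×21 (coexistence checks) and 41×41 (library default);
dynamic-function-map contrast 9×9 gain cells × 9×9 stimuli; codim-2
traces over ~6–11 `Hᵢ` values; branch continuation over −50…120 s⁻¹ with
step cap 0.5 (weighted units); demo runs 8.5 s at 1 ms. Event
localization 0.01 s⁻¹; eigenvalue zero threshold 1e−4 s⁻¹; oscillation
flag 0.5 mV peak-to-peak; equilibrium dedup 1e−6 mV. These sizes were
chosen so the full suite exercises every mechanism at the scale where
its qualitative structure is stable under refinement (labels unchanged
at dt/2, events stable under step-cap changes).

## Known limitations

No conduction delays, neural-field extent, or plasticity; no limit-cycle
continuation (global cycle structure is only probed by simulation); Hopf
criticality by probing rather than normal form; the two-population
mapping constant `N_PP = 113.4` is adopted, not re-derived; the parsing
network handles one sentence, single word mentions, and no
morphosyntax, and must be reset externally between sentences.
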