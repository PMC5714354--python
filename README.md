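# canmicro

A simulator and analysis toolkit for a generalized **canonical-microcircuit
neural mass model**: three coupled cortical populations — pyramidal cells
(Py), excitatory interneurons (EIN) and inhibitory interneurons (IIN) —
whose feedback topology can be blended continuously between a
three-population architecture (indirect excitatory feedback through the
EIN) and two-population architectures (direct Py self-feedback, with or
without recurrent IIN self-inhibition / disinhibition).

The package is for computational neuroscientists studying how two basic
cortical operations — **signal-flow gating** and **bistability-based
working memory** — emerge from local circuit structure and from the
excitation–inhibition balance, and how networks of such microcircuits can
implement sequence processing (the shipped demo parses a syntactically
ambiguous sentence).

## Model

Each synaptic channel convolves its input firing rate with an
alpha-function kernel `h(t) = (H/τ) t e^{-t/τ}`, equivalent to the
critically damped second-order ODE

    V̈ = (H/τ) u − (2/τ) V̇ − V/τ²,

and membrane potential maps to firing rate through the logistic
activation `S(V) = 2e₀ / (1 + e^{r(v₀−V)})`. With channel potentials
V₁…V₅ the circuit reads

    Dₑ V₁ = N_EP φ_P + b₁ p_ext
    Dₑ V₂ = b₁ N_PE φ_E + (1−b₁) N_PP φ_P + (1−b₁) p_ext
    Dᵢ V₃ = N_PI φ_I
    Dₑ V₄ = N_IP φ_P + p_iin
    Dᵢ V₅ = (1−b₂) N_II φ_I

with `φ_P = S(V₂−V₃)`, `φ_E = S(V₁)`, `φ_I = S(V₄−V₅)`. The output is
the pyramidal potential `V_Py = V₂ − V₃`. The architecture weights select
the topology: `(b₁,b₂) = (1,1)` three populations, `(0,1)` two
populations, `(0,0)` two populations with disinhibition. Default
parameters (the `table1` preset): `Hₑ = 3.25 mV`, `Hᵢ = 22 mV`,
`τₑ = 10 ms`, `τᵢ = 20 ms`, `N_EP = 135`, `N_PE = 0.8·N_EP`,
`N_IP = N_PI = 0.25·N_EP`, `N_PP = 113.4`, `N_II = 33.25`,
`e₀ = 2.5 s⁻¹`, `r = 0.56 mV⁻¹`, `v₀ = 6 mV`.

On top of the simulator (fixed-step Heun, 1 ms) the package provides

* **response classification** — a rectangular stimulus is labelled
  *nonresponsive*, *transfer* or *memory* by comparing the maximum of
  `V_Py` against a 4 mV firing threshold in prestimulus, immediate and
  asymptotic windows; grids of such runs form *fingerprints* and
  *dynamic function maps* over the (Hₑ, Hᵢ) balance plane;
* **bifurcation analysis** — equilibrium curves by pseudo-arclength
  continuation with eigenvalue-based stability, detection and typing of
  fold (saddle-node vs saddle-saddle) and Hopf (sub/supercritical)
  points, and tracing of the fold loci at zero drive through the
  (Hₑ, Hᵢ) plane;
* **microcircuit networks** — excitatory coupling onto the afferent
  input route, inhibitory coupling onto the IIN (the reset route), noisy
  contextual inhibition, and a six-node sentence-parsing demonstration.

## Worked example

```
$ canmicro branch --preset table1 --pext -50:120 --out-dir out
fold_sn at p_ext = 78.25 s^-1 (V_Py = 1.18 mV)
fold_ss at p_ext = -29.91 s^-1 (V_Py = 5.60 mV)
hopf_sub at p_ext = -5.31 s^-1 (V_Py = 6.04 mV)
```

The default three-population circuit has an S-shaped fixed-point curve.
At rest (`p_ext = 0`) it sits on the lower branch at `V_Py ≈ −1.9 mV`:

```
$ canmicro simulate --preset table1 --intensity 0 --duration 0 --out-dir out
final V_Py = -1.904 mV, behavior = nonresponsive
```

The saddle-node fold at `p_ext ≈ 78 s⁻¹` is the perception threshold:
weaker pulses cannot move the circuit off the lower branch, stronger ones
drive it above the 4 mV firing threshold, and pulses that outlast the
damped oscillation latch the circuit on the upper branch (working
memory), protected by the bistability between the folds. A brief drive to
the IIN resets it. The sentence demo composes six such circuits:

```
$ canmicro parse-demo --context high --out-dir out
outcome: object_modifier; active nodes: ['I', 'hit', 'thief', 'with_o', 'club']
```

With strong contextual inhibition of the verb-modifier node, the phrase
"with the club" binds to the object ("the thief with the club"); with
`--context low` the verb-modifier wins instead, and raising `--hi` to
23–24 mV on all nodes breaks the parse entirely.

Python API equivalents live in `canmicro.simulate`, `canmicro.classify`,
`canmicro.bifurcation` and `canmicro.network`; every CLI run writes CSV
data, JSON sidecars and a `manifest.json` with checksums.

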