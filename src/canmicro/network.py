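"""Networks of interacting microcircuits and the sentence-parsing demo.

Nodes are full canonical microcircuits.  Excitatory inter-node coupling
adds ``gain * phi_P(source)`` to the target's external-input route;
inhibitory coupling drives the target's IIN (the same route that resets a
latched circuit).  Contextual information enters as a noisy inhibitory
offset that degrades the afferent input of its target (subtracted from
p_ext, floored at zero).

The shipped six-node demo parses the syntactically ambiguous sentence
"I hit the thief with the club".  Word-representing nodes are grouped
into modules (subject, verb, object and their modifiers); the two 'with'
nodes compete through asymmetric mutual inhibition, and the present level
of contextual inhibition on the verb-modifier decides which interpretation
survives.  Inter-node weights are hand-tuned calibration artifacts chosen
to reproduce the qualitative parsing outcomes, not measured quantities.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bifurcation, model, simulate
from .model import ModelParams

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "ContextChannel",
    "NetworkSpec",
    "WordEvent",
    "WordSchedule",
    "ParseOutcome",
    "ParseTrace",
    "simulate_network",
    "preactivation_level",
    "balance_perturbation_experiment",
    "sentence_demo",
    "load_network_yaml",
]

U_TH = 4.0  # firing threshold (mV) used for final activation bits

MODULES = ("S", "V", "V-mod", "O", "O-mod")


@dataclass(frozen=True)
class NodeSpec:
    name: str
    module: str
    params: ModelParams = field(default_factory=ModelParams.table1)

    def __post_init__(self):
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}; valid: {MODULES}")


@dataclass(frozen=True)
class EdgeSpec:
    source: str
    target: str
    sign: str                   # "excitatory" | "inhibitory"
    gain: float

    def __post_init__(self):
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"edge sign must be excitatory/inhibitory, got {self.sign!r}")
        if self.gain < 0:
            raise ValueError(f"edge gain must be >= 0, got {self.gain}")


@dataclass(frozen=True)
class ContextChannel:
    """Noisy inhibitory signal degrading a node's afferent input."""

    target: str
    offset: float               # mean subtracted drive, s^-1
    noise_sd: float             # per-step Gaussian SD, s^-1

    def __post_init__(self):
        if self.offset < 0 or self.noise_sd < 0:
            raise ValueError("context offset and noise_sd must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...] = ()
    context_channels: tuple[ContextChannel, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "context_channels", tuple(self.context_channels))
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        known = set(names)
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in known:
                    raise ValueError(f"edge references unknown node {end!r}")
        for c in self.context_channels:
            if c.target not in known:
                raise ValueError(f"context channel targets unknown node {c.target!r}")

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def with_param(self, **flat: float) -> "NetworkSpec":
        """Apply a flat parameter override to every node (e.g. ``Hi=23``)."""
        return dc_replace(self, nodes=tuple(
            dc_replace(n, params=n.params.replace(**flat)) for n in self.nodes))


@dataclass(frozen=True)
class WordEvent:
    node: str
    onset: float
    duration: float
    intensity: float

    def __post_init__(self):
        if self.onset < 0 or self.duration < 0 or self.intensity < 0:
            raise ValueError("word event onset/duration/intensity must be >= 0")


@dataclass(frozen=True)
class WordSchedule:
    events: tuple[WordEvent, ...]

    def __post_init__(self):
        object.__setattr__(self, "events",
                           tuple(sorted(self.events, key=lambda e: e.onset)))

    @property
    def end_time(self) -> float:
        return max((e.onset + e.duration for e in self.events), default=0.0)

    def scheduled_nodes(self) -> set[str]:
        return {e.node for e in self.events}


class ParseOutcome(enum.Enum):
    INTERPRETATION_A = "object_modifier"    # 'with the club' modifies the object
    INTERPRETATION_B = "verb_modifier"      # 'with the club' modifies the verb
    DEFECTIVE = "defective"
    MEMORY_LOSS = "memory_loss"


@dataclass
class ParseTrace:
    t: np.ndarray
    v_py: np.ndarray            # (n, n_nodes)
    node_names: list[str]
    active: np.ndarray          # (n_nodes,) final activation bits
    outcome: ParseOutcome
    resting_v_py: np.ndarray    # (n_nodes,) isolated low-state baseline
    schedule: WordSchedule
    spec: NetworkSpec
    metadata: dict = field(default_factory=dict)

    def node_v_py(self, name: str) -> np.ndarray:
        return self.v_py[:, self.node_names.index(name)]

    def active_nodes(self) -> list[str]:
        return [n for n, a in zip(self.node_names, self.active) if a]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.v_py, columns=self.node_names)
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def parse_outcome(spec: NetworkSpec, schedule: WordSchedule,
                  active: np.ndarray) -> ParseOutcome:
    """Pure function of the final activation bits and the expected words."""
    names = spec.node_names
    active_set = {n for n, a in zip(names, active) if a}
    if not active_set:
        return ParseOutcome.MEMORY_LOSS
    mod_v = {n.name for n in spec.nodes if n.module == "V-mod"}
    mod_o = {n.name for n in spec.nodes if n.module == "O-mod"}
    core = schedule.scheduled_nodes() - mod_v - mod_o
    v_on = bool(active_set & mod_v)
    o_on = bool(active_set & mod_o)
    if core <= active_set and o_on and not v_on:
        return ParseOutcome.INTERPRETATION_A
    if core <= active_set and v_on and not o_on:
        return ParseOutcome.INTERPRETATION_B
    return ParseOutcome.DEFECTIVE


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_network(
    spec: NetworkSpec,
    schedule: WordSchedule,
    dt: float = simulate.DEFAULT_DT,
    seed: int | None = 0,
    total_time: float | None = None,
    *,
    asymptotic_window: float = 1.0,
) -> ParseTrace:
    """Integrate all nodes jointly and judge the final parse.

    Word drives and context noise are frozen per step; the state-dependent
    inter-node coupling is evaluated at both Heun stages.  The final
    activation bit of a node is whether its ``V_Py`` exceeds the firing
    threshold at any time in the last ``asymptotic_window`` seconds.
    """
    n_nodes = len(spec.nodes)
    if n_nodes == 0:
        raise ValueError("network has no nodes")
    if total_time is None:
        total_time = schedule.end_time + 2.5
    n_steps = int(round(total_time / dt))
    names = spec.node_names
    idx = {n: i for i, n in enumerate(names)}

    # per-node kernel coefficients (parameters may differ across nodes)
    H = np.stack([n.params.kernel_arrays()[0] for n in spec.nodes])
    tau = np.stack([n.params.kernel_arrays()[1] for n in spec.nodes])
    Hdt, two_dt, inv_t2 = H / tau, 2.0 / tau, 1.0 / tau**2
    g0 = spec.nodes[0].params
    gains = np.array([[n.params.gains.N_EP, n.params.gains.N_PE,
                       n.params.gains.N_PI, n.params.gains.N_IP,
                       n.params.gains.N_II] for n in spec.nodes])
    b1 = np.array([n.params.arch.b1 for n in spec.nodes])
    b2 = np.array([n.params.arch.b2 for n in spec.nodes])
    n_pp = np.array([n.params.gains.N_PP for n in spec.nodes])
    sp = g0.sigmoid
    two_e0, r, v0 = 2.0 * sp.e0, sp.r, sp.v0

    A_exc = np.zeros((n_nodes, n_nodes))
    A_inh = np.zeros((n_nodes, n_nodes))
    for e in spec.edges:
        M = A_exc if e.sign == "excitatory" else A_inh
        M[idx[e.target], idx[e.source]] += e.gain

    word = np.zeros((n_steps, n_nodes))
    tk = np.arange(n_steps) * dt
    for ev in schedule.events:
        if ev.node not in idx:
            raise ValueError(f"schedule references unknown node {ev.node!r}")
        word[(tk >= ev.onset) & (tk < ev.onset + ev.duration), idx[ev.node]] += ev.intensity

    rng = np.random.default_rng(seed)
    ctx_targets = np.array([idx[c.target] for c in spec.context_channels], dtype=int)
    ctx_offset = np.array([c.offset for c in spec.context_channels])
    ctx_sd = np.array([c.noise_sd for c in spec.context_channels])

    def sig(v):
        return two_e0 / (1.0 + np.exp(np.clip(r * (v0 - v), -500, 500)))

    def rhs_fn(Y, pe, pi):
        V, W = Y[:, :5], Y[:, 5:]
        phi_p = sig(V[:, 1] - V[:, 2])
        phi_e = sig(V[:, 0])
        phi_i = sig(V[:, 3] - V[:, 4])
        pe_tot = np.maximum(0.0, pe + A_exc @ phi_p)
        pi_tot = pi + A_inh @ phi_p
        u = np.empty_like(V)
        u[:, 0] = gains[:, 0] * phi_p + b1 * pe_tot
        u[:, 1] = b1 * gains[:, 1] * phi_e + (1.0 - b1) * n_pp * phi_p \
            + (1.0 - b1) * pe_tot
        u[:, 2] = gains[:, 2] * phi_i
        u[:, 3] = gains[:, 3] * phi_p + pi_tot
        u[:, 4] = (1.0 - b2) * gains[:, 4] * phi_i
        return np.concatenate([W, Hdt * u - two_dt * W - inv_t2 * V], axis=1)

    def drive(k):
        pe = word[k].copy()
        if ctx_targets.size:
            draw = ctx_offset + ctx_sd * rng.standard_normal(ctx_targets.size)
            np.subtract.at(pe, ctx_targets, draw)
        return pe, np.zeros(n_nodes)

    try:
        vpy, _ = simulate.heun_core(np.zeros((n_nodes, model.STATE_DIM)),
                                    n_steps, dt, drive, rhs_fn,
                                    record="vpy", check_every=50)
    except simulate.IntegrationError as err:
        raise simulate.IntegrationError(f"network blow-up: {err}") from err

    t = np.arange(n_steps + 1) * dt
    asym = vpy[t >= total_time - asymptotic_window]
    active = asym.max(axis=0) > U_TH
    resting = np.array([_resting_v_py(n.params) for n in spec.nodes])
    return ParseTrace(
        t=t, v_py=vpy, node_names=names, active=active,
        outcome=parse_outcome(spec, schedule, active),
        resting_v_py=resting, schedule=schedule, spec=spec,
        metadata={"dt": dt, "seed": seed, "total_time": total_time})


_RESTING_CACHE: dict[tuple, float] = {}


def _resting_v_py(p: ModelParams) -> float:
    key = tuple(sorted(model.params_to_dict(p).items()))
    if key not in _RESTING_CACHE:
        eqs = bifurcation.find_equilibria(0.0, p)
        stab = [e for e in eqs if e.stable]
        _RESTING_CACHE[key] = (stab[0].v_py if stab else eqs[0].v_py)
    return _RESTING_CACHE[key]


def preactivation_level(
    trace: ParseTrace,
    node: str,
    window: tuple[float, float] | None = None,
) -> float:
    """Sub-threshold baseline shift of a node, in mV.

    Measured as the mean ``V_Py`` in the node's prestimulus window (the
    0.5 s before its first word input by default) minus its isolated
    resting potential.  Upstream activity pre-activates the node, pushing
    it toward its fold bifurcation without crossing the firing threshold;
    the measurement is undefined (raises) if the node is active in the
    window.
    """
    i = trace.node_names.index(node)
    if window is None:
        onsets = [e.onset for e in trace.schedule.events if e.node == node]
        if not onsets:
            raise ValueError(f"node {node!r} has no scheduled word; pass a window")
        window = (max(0.0, min(onsets) - 0.5), min(onsets))
    mask = (trace.t >= window[0]) & (trace.t <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} outside trace span")
    seg = trace.v_py[mask, i]
    if seg.max() > U_TH:
        raise ValueError(
            f"node {node!r} is active in window {window}; "
            "pre-activation is only defined for inactive nodes")
    return float(seg.mean() - trace.resting_v_py[i])


def balance_perturbation_experiment(
    spec: NetworkSpec,
    schedule: WordSchedule,
    Hi_values: Sequence[float],
    seed: int | None = 0,
    dt: float = simulate.DEFAULT_DT,
) -> dict[float, ParseTrace]:
    """Re-run the parse with the inhibitory gain shifted on every node.

    A uniform increase of Hi biases the local balance toward inhibition;
    the microcircuits lose the bistability their sustained activation
    relies on and the structure-building process breaks down.
    """
    out = {}
    for hi in Hi_values:
        out[float(hi)] = simulate_network(spec.with_param(Hi=float(hi)),
                                          schedule, dt=dt, seed=seed)
    return out


# ---------------------------------------------------------------------------
# YAML I/O and the shipped demo
# ---------------------------------------------------------------------------

def load_network_yaml(source) -> tuple[NetworkSpec, WordSchedule]:
    """Read a network spec + word schedule from YAML (path or mapping)."""
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    base = model.params_from_dict(doc.get("params", {}) or {})
    nodes = []
    for nd in doc.get("nodes", []):
        p = base if "params" not in nd else model.params_from_dict(
            {**model.params_to_dict(base), **nd["params"]})
        nodes.append(NodeSpec(name=nd["name"], module=nd["module"], params=p))
    edges = [EdgeSpec(source=e["source"], target=e["target"],
                      sign=e["sign"], gain=float(e["gain"]))
             for e in doc.get("edges", [])]
    ctx = [ContextChannel(target=c["target"], offset=float(c["offset"]),
                          noise_sd=float(c["noise_sd"]))
           for c in doc.get("context", [])]
    sched = WordSchedule(tuple(
        WordEvent(node=e["node"], onset=float(e["onset"]),
                  duration=float(e["duration"]), intensity=float(e["intensity"]))
        for e in doc.get("schedule", [])))
    return NetworkSpec(tuple(nodes), tuple(edges), tuple(ctx)), sched


def sentence_demo(
    context: str = "high",
    Hi: float = 22.0,
    context_offset: float | None = None,
) -> tuple[NetworkSpec, WordSchedule]:
    """The shipped six-node demo for "I hit the thief with the club".

    ``context="high"`` applies the calibrated inhibitory context signal
    to the verb-modifier node (selects the object-modifier reading);
    ``context="low"`` removes it (the verb-modifier wins through the
    asymmetric mutual inhibition).  ``context_offset`` overrides the
    offset explicitly; noise SD is 10 % of the offset.
    """
    if context not in ("high", "low"):
        raise ValueError("context must be 'high' or 'low'")
    with resources.files("canmicro.data").joinpath("sentence_demo.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    if context_offset is None:
        context_offset = float(doc["context_levels"][context])
    doc = dict(doc)
    doc["context"] = ([{"target": doc["context_target"],
                        "offset": context_offset,
                        "noise_sd": 0.1 * context_offset}]
                      if context_offset > 0 else [])
    spec, sched = load_network_yaml(doc)
    if Hi != 22.0:
        spec = spec.with_param(Hi=Hi)
    return spec, sched
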