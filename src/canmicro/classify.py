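"""Response-behavior classification, fingerprints and dynamic function maps.

A stimulated microcircuit is classified by comparing the maximum of
``V_Py`` against a firing threshold (4 mV by default) in three windows:
prestimulus (0.5-1 s), immediate response (1.1-3.5 s) and asymptotic
(4-5 s).  The activation bit triple maps onto three behaviors:

* MEMORY        -- active in the asymptotic window (the circuit latched),
* TRANSFER      -- active only in the immediate response window,
* NONRESPONSIVE -- uniformly below (or uniformly above) threshold.

The maximum criterion deliberately counts activity that oscillates about
the threshold as active: such a population drives its targets during part
of every cycle.  Grids of classified runs over stimulus intensity and
duration form a *fingerprint*; summarizing fingerprints over the synaptic
gain plane (He, Hi) yields a *dynamic function map*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import bifurcation, model, simulate
from .model import ModelParams
from .simulate import DEFAULT_DT, Trajectory, heun_core, make_rhs

__all__ = [
    "Behavior",
    "WindowSpec",
    "BehaviorLabel",
    "BehaviorMap",
    "DynamicFunctionMap",
    "DeactivationMap",
    "classify_response",
    "fingerprint",
    "dynamic_function_map",
    "deactivation_map",
    "stimulus_offset_phase_scan",
]

#: asymptotic-window peak-to-peak V_Py above this flags an oscillatory state
OSCILLATION_PTP = 0.5  # mV


class Behavior(enum.Enum):
    NONRESPONSIVE = "nonresponsive"
    TRANSFER = "transfer"
    MEMORY = "memory"

    def __str__(self) -> str:  # compact CSV labels
        return self.value


@dataclass(frozen=True)
class WindowSpec:
    """Classification windows (s) and firing threshold (mV)."""

    prestimulus: tuple[float, float] = (0.5, 1.0)
    immediate: tuple[float, float] = (1.1, 3.5)
    asymptotic: tuple[float, float] = (4.0, 5.0)
    threshold: float = 4.0

    def __post_init__(self):
        w = [self.prestimulus, self.immediate, self.asymptotic]
        for a, b in w:
            if not a < b:
                raise ValueError(f"window ({a}, {b}) is empty")
        for (_, b), (a2, _) in zip(w, w[1:]):
            if b > a2:
                raise ValueError("classification windows must be disjoint and ordered")

    @property
    def windows(self) -> tuple[tuple[float, float], ...]:
        return (self.prestimulus, self.immediate, self.asymptotic)

    def step_windows(self, dt: float) -> list[tuple[int, int]]:
        """Inclusive sample-index windows on a uniform grid."""
        out = []
        for a, b in self.windows:
            out.append((int(np.ceil(a / dt - 1e-9)), int(np.floor(b / dt + 1e-9))))
        return out


@dataclass(frozen=True)
class BehaviorLabel:
    behavior: Behavior
    bits: tuple[int, int, int]
    oscillatory: bool = False
    warning: str | None = None


_EXOTIC = "activation triple not produced by rectangular protocols"


def _label_from_bits(pre: int, imm: int, asym: int) -> tuple[Behavior, str | None]:
    """Pure mapping from the activation triple to a behavior.

    A uniform triple means the stimulus changed nothing (inactive
    throughout, or a parameterization that is permanently above
    threshold): nonresponsive.  Otherwise asymptotic activity means the
    circuit latched (memory) and immediate-only activity is transfer.
    Non-uniform triples with prestimulus activity ((1,1,0), (1,0,*))
    cannot arise from a settled start plus a rectangular pulse; they map
    to NONRESPONSIVE with a warning.
    """
    if pre == imm == asym:
        return Behavior.NONRESPONSIVE, None
    if pre:
        return Behavior.NONRESPONSIVE, _EXOTIC
    if asym:
        return Behavior.MEMORY, None
    return Behavior.TRANSFER, None


def classify_response(traj: Trajectory, w: WindowSpec = WindowSpec()) -> BehaviorLabel:
    """Classify a single trajectory by the three-window threshold rule."""
    if traj.t[-1] + 1e-9 < w.asymptotic[1]:
        raise ValueError(
            f"trajectory ends at {traj.t[-1]:.3f} s, before the asymptotic "
            f"window {w.asymptotic}")
    maxima = [traj.window_max(*win) for win in w.windows]
    bits = tuple(int(m > w.threshold) for m in maxima)
    behavior, warning = _label_from_bits(*bits)
    a, b = w.asymptotic
    mask = (traj.t >= a) & (traj.t <= b)
    osc = bool(np.ptp(traj.v_py[mask]) > OSCILLATION_PTP)
    return BehaviorLabel(behavior=behavior, bits=bits, oscillatory=osc, warning=warning)


# ---------------------------------------------------------------------------
# batched grid classification
# ---------------------------------------------------------------------------

def _classify_batch(
    rhs_fn,
    intensities: np.ndarray,
    durations: np.ndarray,
    *,
    dt: float,
    w: WindowSpec,
    settle_time: float,
    total_time: float,
):
    """Run one stimulated trajectory per (intensity, duration) row and
    return (labels, bits, osc) arrays; rows are independent."""
    n = intensities.size
    n_steps = int(round(total_time / dt))
    k_on = int(round(settle_time / dt))
    k_off = k_on + np.round(durations / dt).astype(int)
    zeros = np.zeros(n)

    def drive(k):
        pe = np.where((k >= k_on) & (k < k_off), intensities, 0.0)
        return pe, zeros

    windows = w.step_windows(dt)
    (wmax, wmin), _ = heun_core(np.zeros((n, model.STATE_DIM)), n_steps, dt,
                                drive, rhs_fn, record="windows", windows=windows)
    bits = (wmax > w.threshold).astype(int)  # (3, n)
    labels = np.empty(n, dtype=object)
    warn = np.zeros(n, dtype=bool)
    for i in range(n):
        labels[i], wmsg = _label_from_bits(bits[0, i], bits[1, i], bits[2, i])
        warn[i] = wmsg is not None
    osc = (wmax[2] - wmin[2]) > OSCILLATION_PTP
    return labels, bits.T, osc, warn


@dataclass
class BehaviorMap:
    """Behavior labels on a 2-D stimulus grid (a *fingerprint*)."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    labels: np.ndarray          # (n1, n2) of Behavior
    bits: np.ndarray            # (n1, n2, 3)
    oscillatory: np.ndarray     # (n1, n2) bool
    metadata: dict = field(default_factory=dict)

    def behavior_set(self) -> frozenset[Behavior]:
        return frozenset(self.labels.ravel())

    def modal_behavior(self) -> Behavior:
        flat = list(self.labels.ravel())
        return max(set(flat), key=flat.count)

    def counts(self) -> dict[Behavior, int]:
        flat = list(self.labels.ravel())
        return {b: flat.count(b) for b in Behavior}

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame({
            self.axis1_name: a1.ravel(),
            self.axis2_name: a2.ravel(),
            "label": [str(b) for b in self.labels.ravel()],
            "bits": ["".join(map(str, b)) for b in self.bits.reshape(-1, 3)],
            "osc_flag": self.oscillatory.ravel().astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def fingerprint(
    p: ModelParams,
    intensities: Sequence[float] | None = None,
    durations: Sequence[float] | None = None,
    *,
    dt: float = DEFAULT_DT,
    w: WindowSpec = WindowSpec(),
    settle_time: float = simulate.DEFAULT_SETTLE_TIME,
    total_time: float = simulate.DEFAULT_TOTAL_TIME,
) -> BehaviorMap:
    """Characteristic fingerprint: behaviors over intensity x duration.

    Defaults cover 50-250 s^-1 and 0.5-1.5 s at 41 x 41 resolution.  Each
    cell is one deterministic noise-free simulation; cells are mutually
    independent so the grid evaluation order is irrelevant.
    """
    ints = np.asarray(intensities if intensities is not None
                      else np.linspace(50.0, 250.0, 41), dtype=float)
    durs = np.asarray(durations if durations is not None
                      else np.linspace(0.5, 1.5, 41), dtype=float)
    if ints.size == 0 or durs.size == 0:
        raise ValueError("intensity and duration grids must be nonempty")
    I, D = np.meshgrid(ints, durs, indexing="ij")
    labels, bits, osc, _ = _classify_batch(
        make_rhs(p), I.ravel(), D.ravel(),
        dt=dt, w=w, settle_time=settle_time, total_time=total_time)
    shape = I.shape
    return BehaviorMap(
        axis1_name="intensity", axis1=ints,
        axis2_name="duration", axis2=durs,
        labels=labels.reshape(shape),
        bits=bits.reshape(shape + (3,)),
        oscillatory=osc.reshape(shape),
        metadata={"params": model.params_to_dict(p), "dt": dt,
                  "threshold": w.threshold},
    )


@dataclass
class DynamicFunctionMap:
    """Fingerprint summaries over the synaptic-gain plane.

    Each (He, Hi) cell is reduced to the sorted set of behaviors present
    in its fingerprint plus the modal behavior; the sorted set is the
    map's cell category.
    """

    He: np.ndarray
    Hi: np.ndarray
    behavior_sets: np.ndarray   # (nHe, nHi) of frozenset[Behavior]
    modal: np.ndarray           # (nHe, nHi) of Behavior
    counts: np.ndarray          # (nHe, nHi, 3) cell counts per behavior
    metadata: dict = field(default_factory=dict)

    def category(self, i: int, j: int) -> tuple[str, ...]:
        order = [Behavior.NONRESPONSIVE, Behavior.TRANSFER, Behavior.MEMORY]
        return tuple(str(b) for b in order if b in self.behavior_sets[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, he in enumerate(self.He):
            for j, hi in enumerate(self.Hi):
                rows.append({
                    "He": he, "Hi": hi,
                    "behaviors": "+".join(self.category(i, j)),
                    "modal": str(self.modal[i, j]),
                    "n_nonresponsive": int(self.counts[i, j, 0]),
                    "n_transfer": int(self.counts[i, j, 1]),
                    "n_memory": int(self.counts[i, j, 2]),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def dynamic_function_map(
    He_grid: Sequence[float],
    Hi_grid: Sequence[float],
    base: ModelParams,
    intensities: Sequence[float] | None = None,
    durations: Sequence[float] | None = None,
    *,
    dt: float = DEFAULT_DT,
    w: WindowSpec = WindowSpec(),
) -> DynamicFunctionMap:
    """Fingerprint summary for every (He, Hi) combination.

    The per-cell stimulus grid defaults to a coarse 9 x 9 sampling of the
    standard ranges; all simulations across all cells run as one batch.
    """
    He_grid = np.asarray(He_grid, dtype=float)
    Hi_grid = np.asarray(Hi_grid, dtype=float)
    if He_grid.size == 0 or Hi_grid.size == 0:
        raise ValueError("He and Hi grids must be nonempty")
    ints = np.asarray(intensities if intensities is not None
                      else np.linspace(50.0, 250.0, 9), dtype=float)
    durs = np.asarray(durations if durations is not None
                      else np.linspace(0.5, 1.5, 9), dtype=float)

    HeG, HiG, IG, DG = np.meshgrid(He_grid, Hi_grid, ints, durs, indexing="ij")
    shape4 = HeG.shape
    n = HeG.size

    # per-row kernel coefficients; only He/Hi vary across rows
    _, tau = base.kernel_arrays()
    Hrows = np.stack([HeG.ravel(), HeG.ravel(), HiG.ravel(),
                      HeG.ravel(), HiG.ravel()], axis=1)
    Hdt = Hrows / tau
    two_dt = 2.0 / tau
    inv_t2 = 1.0 / tau**2
    g, a, sp = base.gains, base.arch, base.sigmoid
    two_e0, r, v0 = 2.0 * sp.e0, sp.r, sp.v0
    b1, b2 = a.b1, a.b2

    def rhs_fn(Y, pe, pi):
        V, W = Y[:, :5], Y[:, 5:]
        phi_p = two_e0 / (1.0 + np.exp(np.clip(r * (v0 - (V[:, 1] - V[:, 2])), -500, 500)))
        phi_e = two_e0 / (1.0 + np.exp(np.clip(r * (v0 - V[:, 0]), -500, 500)))
        phi_i = two_e0 / (1.0 + np.exp(np.clip(r * (v0 - (V[:, 3] - V[:, 4])), -500, 500)))
        u = np.empty_like(V)
        u[:, 0] = g.N_EP * phi_p + b1 * pe
        u[:, 1] = b1 * g.N_PE * phi_e + (1.0 - b1) * g.N_PP * phi_p + (1.0 - b1) * pe
        u[:, 2] = g.N_PI * phi_i
        u[:, 3] = g.N_IP * phi_p + pi
        u[:, 4] = (1.0 - b2) * g.N_II * phi_i
        return np.concatenate([W, Hdt * u - two_dt * W - inv_t2 * V], axis=1)

    labels, _, _, _ = _classify_batch_with_rhs(
        rhs_fn, IG.ravel(), DG.ravel(), n, dt=dt, w=w)
    labels4 = labels.reshape(shape4)

    nHe, nHi = He_grid.size, Hi_grid.size
    sets = np.empty((nHe, nHi), dtype=object)
    modal = np.empty((nHe, nHi), dtype=object)
    counts = np.zeros((nHe, nHi, 3), dtype=int)
    order = [Behavior.NONRESPONSIVE, Behavior.TRANSFER, Behavior.MEMORY]
    for i in range(nHe):
        for j in range(nHi):
            flat = list(labels4[i, j].ravel())
            sets[i, j] = frozenset(flat)
            modal[i, j] = max(set(flat), key=flat.count)
            for c, b in enumerate(order):
                counts[i, j, c] = flat.count(b)
    return DynamicFunctionMap(
        He=He_grid, Hi=Hi_grid, behavior_sets=sets, modal=modal, counts=counts,
        metadata={"base_params": model.params_to_dict(base),
                  "intensities": ints.tolist(), "durations": durs.tolist(),
                  "dt": dt})


def _classify_batch_with_rhs(rhs_fn, intensities, durations, n, *, dt, w,
                             settle_time=simulate.DEFAULT_SETTLE_TIME,
                             total_time=simulate.DEFAULT_TOTAL_TIME):
    n_steps = int(round(total_time / dt))
    k_on = int(round(settle_time / dt))
    k_off = k_on + np.round(np.asarray(durations) / dt).astype(int)
    ints = np.asarray(intensities, dtype=float)
    zeros = np.zeros(n)

    def drive(k):
        return np.where((k >= k_on) & (k < k_off), ints, 0.0), zeros

    windows = w.step_windows(dt)
    (wmax, wmin), _ = heun_core(np.zeros((n, model.STATE_DIM)), n_steps, dt,
                                drive, rhs_fn, record="windows", windows=windows)
    bits = (wmax > w.threshold).astype(int)
    labels = np.empty(n, dtype=object)
    warn = np.zeros(n, dtype=bool)
    for i in range(n):
        labels[i], wmsg = _label_from_bits(bits[0, i], bits[1, i], bits[2, i])
        warn[i] = wmsg is not None
    osc = (wmax[2] - wmin[2]) > OSCILLATION_PTP
    return labels, bits.T, osc, warn


# ---------------------------------------------------------------------------
# deactivation diagram
# ---------------------------------------------------------------------------

@dataclass
class DeactivationMap:
    """Outcome of IIN reset impulses applied to the latched high state."""

    intensities: np.ndarray
    durations: np.ndarray
    deactivated: np.ndarray     # (nI, nD) bool
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.intensities, self.durations, indexing="ij")
        return pd.DataFrame({
            "iin_intensity": a1.ravel(),
            "iin_duration": a2.ravel(),
            "deactivated": self.deactivated.ravel().astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def deactivation_map(
    p: ModelParams,
    iin_intensities: Sequence[float] | None = None,
    iin_durations: Sequence[float] | None = None,
    *,
    dt: float = DEFAULT_DT,
    threshold: float = 4.0,
    memory_pulse: tuple[float, float] = (150.0, 1.5),
) -> DeactivationMap:
    """Map which IIN impulses clear the memory trace.

    The circuit is first driven into the high state by a memory-inducing
    external pulse (1-2.5 s); the IIN impulse starts at 4.5 s and the
    asymptotic judgement window is 7-8 s of an 8 s run.  Requires a
    parameterization that is bistable at zero input.
    """
    state = bifurcation.bistability_check(p, 0.0)
    if state == "monostable":
        raise ValueError(
            "deactivation_map requires bistability at p_ext = 0 "
            "(bifurcation.bistability_check reported 'monostable')")
    ints = np.asarray(iin_intensities if iin_intensities is not None
                      else np.linspace(0.0, 100.0, 11), dtype=float)
    durs = np.asarray(iin_durations if iin_durations is not None
                      else np.linspace(0.01, 0.2, 11), dtype=float)
    I, D = np.meshgrid(ints, durs, indexing="ij")
    n = I.size
    total_time, iin_onset = 8.0, 4.5
    n_steps = int(round(total_time / dt))
    k_on = int(round(simulate.DEFAULT_SETTLE_TIME / dt))
    k_off = k_on + int(round(memory_pulse[1] / dt))
    ki_on = int(round(iin_onset / dt))
    ki_off = ki_on + np.round(D.ravel() / dt).astype(int)
    iflat = I.ravel()

    def drive(k):
        pe = np.full(n, memory_pulse[0]) if k_on <= k < k_off else np.zeros(n)
        pi = np.where((k >= ki_on) & (k < ki_off), iflat, 0.0)
        return pe, pi

    # windows: pre-impulse check (3.8-4.4 s) and asymptotic (7-8 s)
    wins = [(int(3.8 / dt), int(4.4 / dt)), (int(7.0 / dt), int(8.0 / dt))]
    (wmax, _), _ = heun_core(np.zeros((n, model.STATE_DIM)), n_steps, dt,
                             drive, make_rhs(p), record="windows", windows=wins)
    if not np.all(wmax[0] > threshold):
        raise RuntimeError(
            "memory-inducing pulse failed to latch the circuit; choose a "
            "stronger/longer memory_pulse for this parameterization")
    deact = (wmax[1] <= threshold).reshape(I.shape)
    return DeactivationMap(
        intensities=ints, durations=durs, deactivated=deact,
        metadata={"params": model.params_to_dict(p), "dt": dt,
                  "bistability": state, "memory_pulse": memory_pulse})


def stimulus_offset_phase_scan(
    p: ModelParams,
    intensity: float = 100.0,
    durations: Sequence[float] | None = None,
    *,
    dt: float = DEFAULT_DT,
    w: WindowSpec = WindowSpec(),
) -> list[BehaviorLabel]:
    """Fine duration scan showing the stimulus-offset phase dependence.

    Around the transfer/memory boundary the outcome alternates with the
    phase of the intrinsic oscillation at stimulus switch-off; the default
    scan covers 600-750 ms at 5 ms steps with 100 s^-1 intensity.
    """
    durs = np.asarray(durations if durations is not None
                      else np.arange(0.600, 0.7501, 0.005), dtype=float)
    labels, bits, osc, warn = _classify_batch(
        make_rhs(p), np.full(durs.size, float(intensity)), durs,
        dt=dt, w=w, settle_time=simulate.DEFAULT_SETTLE_TIME,
        total_time=simulate.DEFAULT_TOTAL_TIME)
    return [BehaviorLabel(behavior=labels[i], bits=tuple(bits[i]),
                          oscillatory=bool(osc[i]),
                          warning=_EXOTIC if warn[i] else None)
            for i in range(durs.size)]
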