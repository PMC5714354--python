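"""Time-domain integration of a microcircuit under stimulus protocols.

Integration uses the explicit two-stage Heun scheme (Euler predictor,
trapezoidal corrector) with a fixed step, 1 ms by default.  Drives are
piecewise constant and evaluated once per step, i.e. held through both
stages; when noise is requested it is likewise sampled once per step and
frozen, a simple stochastic-Heun variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import model
from .model import ModelParams, sigmoid

__all__ = [
    "IntegrationError",
    "NoiseSpec",
    "StimulusSegment",
    "StimulusProtocol",
    "Trajectory",
    "heun_core",
    "integrate_heun",
    "run_protocol",
]

DEFAULT_DT = 1e-3  # s
DEFAULT_TOTAL_TIME = 5.0  # s
DEFAULT_SETTLE_TIME = 1.0  # s


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the finite range (numerical blow-up)."""


@dataclass(frozen=True)
class NoiseSpec:
    """Per-step Gaussian fluctuation added to a drive channel."""

    sd: float
    mean: float = 0.0
    target: str = "ext"  # "ext" or "iin"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")
        if self.target not in ("ext", "iin"):
            raise ValueError(f"noise target must be 'ext' or 'iin', got {self.target!r}")


@dataclass(frozen=True)
class StimulusSegment:
    """Rectangular drive segment.

    ``target='ext'`` feeds the architecture-routed external input,
    ``target='iin'`` the additive drive onto the IIN channel (used for
    reset / deactivation experiments).  Active on the half-open interval
    ``[onset, onset + duration)``.
    """

    target: str
    onset: float
    duration: float
    intensity: float

    def __post_init__(self):
        if self.target not in ("ext", "iin"):
            raise ValueError(f"segment target must be 'ext' or 'iin', got {self.target!r}")
        if self.onset < 0:
            raise ValueError(f"segment onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ValueError(f"segment duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class StimulusProtocol:
    segments: tuple[StimulusSegment, ...] = ()
    total_time: float = DEFAULT_TOTAL_TIME
    settle_time: float = DEFAULT_SETTLE_TIME

    def __post_init__(self):
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        object.__setattr__(self, "segments", tuple(self.segments))
        # overlap on the same target is ambiguous for piecewise-constant drives
        for tgt in ("ext", "iin"):
            segs = sorted((s for s in self.segments if s.target == tgt),
                          key=lambda s: s.onset)
            for a, b in zip(segs, segs[1:]):
                if b.onset < a.onset + a.duration:
                    raise ValueError(
                        f"overlapping {tgt!r} segments at onset {b.onset}")

    @classmethod
    def rectangular(cls, intensity: float, duration: float,
                    settle_time: float = DEFAULT_SETTLE_TIME,
                    total_time: float = DEFAULT_TOTAL_TIME) -> "StimulusProtocol":
        """Default protocol: single rectangular external pulse after settling."""
        return cls(segments=(StimulusSegment("ext", settle_time, duration, intensity),),
                   total_time=total_time, settle_time=settle_time)

    def drive_arrays(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant drives per integration step."""
        n = int(round(self.total_time / dt))
        tk = np.arange(n) * dt
        p_ext = np.zeros(n)
        p_iin = np.zeros(n)
        for s in self.segments:
            mask = (tk >= s.onset) & (tk < s.onset + s.duration)
            if s.target == "ext":
                p_ext[mask] += s.intensity
            else:
                p_iin[mask] += s.intensity
        return p_ext, p_iin


@dataclass
class Trajectory:
    """Uniformly sampled trajectory of one microcircuit."""

    t: np.ndarray            # (n,)
    y: np.ndarray            # (n, 10)
    p_ext: np.ndarray        # (n,) drive applied during [t_k, t_{k+1})
    p_iin: np.ndarray        # (n,)
    params: ModelParams
    dt: float

    @property
    def v_py(self) -> np.ndarray:
        return self.y[:, 1] - self.y[:, 2]

    @property
    def v_e(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def v_i(self) -> np.ndarray:
        return self.y[:, 3] - self.y[:, 4]

    def window_max(self, t0: float, t1: float) -> float:
        mask = (self.t >= t0) & (self.t <= t1)
        if not mask.any():
            raise ValueError(f"window ({t0}, {t1}) outside trajectory span")
        return float(self.v_py[mask].max())

    def to_dataframe(self) -> pd.DataFrame:
        sp = self.params.sigmoid
        return pd.DataFrame({
            "t": self.t,
            **{f"V{i+1}": self.y[:, i] for i in range(5)},
            "V_Py": self.v_py,
            "phi_P": sigmoid(self.v_py, sp),
            "phi_E": sigmoid(self.v_e, sp),
            "phi_I": sigmoid(self.v_i, sp),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Heun core
# ---------------------------------------------------------------------------

def heun_core(
    y0: np.ndarray,
    n_steps: int,
    dt: float,
    drive: Callable[[int], tuple[np.ndarray, np.ndarray]],
    rhs_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    *,
    record: str = "vpy",
    windows: Sequence[tuple[int, int]] | None = None,
    check_every: int = 100,
):
    """Batched fixed-step Heun integration.

    ``y0`` has shape (N, 10); ``drive(k)`` returns the frozen per-step
    drives ``(p_ext, p_iin)`` of shape (N,); ``rhs_fn(Y, p_ext, p_iin)``
    the state derivative.  ``record`` selects what is kept:

    * ``"vpy"``  -- V_Py samples, shape (n_steps + 1, N)
    * ``"full"`` -- full states, shape (n_steps + 1, N, 10)
    * ``"windows"`` -- running max/min of V_Py over step-index windows
      ``[k_lo, k_hi]`` (inclusive, sample indices), shapes (n_win, N)

    Returns ``(recorded, y_final)`` where ``recorded`` is the array above
    (for "windows": a ``(win_max, win_min)`` tuple).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    Y = np.array(y0, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != model.STATE_DIM:
        raise ValueError(f"y0 must have shape (N, 10), got {Y.shape}")
    n_batch = Y.shape[0]

    if record == "vpy":
        out = np.empty((n_steps + 1, n_batch))
        out[0] = Y[:, 1] - Y[:, 2]
    elif record == "full":
        out = np.empty((n_steps + 1, n_batch, model.STATE_DIM))
        out[0] = Y
    elif record == "windows":
        if not windows:
            raise ValueError("record='windows' requires windows")
        wmax = np.full((len(windows), n_batch), -np.inf)
        wmin = np.full((len(windows), n_batch), np.inf)
        vp0 = Y[:, 1] - Y[:, 2]
        for w, (klo, khi) in enumerate(windows):
            if klo <= 0 <= khi:
                np.maximum(wmax[w], vp0, out=wmax[w])
                np.minimum(wmin[w], vp0, out=wmin[w])
    else:
        raise ValueError(f"unknown record mode {record!r}")

    for k in range(n_steps):
        pe, pi = drive(k)
        f1 = rhs_fn(Y, pe, pi)
        f2 = rhs_fn(Y + dt * f1, pe, pi)
        Y = Y + (0.5 * dt) * (f1 + f2)
        ks = k + 1  # sample index of the new state
        if record == "vpy":
            out[ks] = Y[:, 1] - Y[:, 2]
        elif record == "full":
            out[ks] = Y
        else:
            vp = Y[:, 1] - Y[:, 2]
            for w, (klo, khi) in enumerate(windows):
                if klo <= ks <= khi:
                    np.maximum(wmax[w], vp, out=wmax[w])
                    np.minimum(wmin[w], vp, out=wmin[w])
        if (k % check_every == 0 or k == n_steps - 1) and not np.all(np.isfinite(Y)):
            bad = np.where(~np.isfinite(Y).all(axis=1))[0]
            raise IntegrationError(
                f"non-finite state at t={ks * dt:.4f} s in batch rows {bad[:5].tolist()}")

    if record == "windows":
        return (wmax, wmin), Y
    return out, Y


def make_rhs(p: ModelParams):
    """Precompiled single-parameterization RHS for the Heun core."""
    H, tau = p.kernel_arrays()
    Hdt = H / tau
    two_dt = 2.0 / tau
    inv_t2 = 1.0 / tau**2
    g, a, sp = p.gains, p.arch, p.sigmoid
    two_e0 = 2.0 * sp.e0
    r, v0 = sp.r, sp.v0
    b1, b2 = a.b1, a.b2

    def rhs_fn(Y, pe, pi):
        V = Y[:, :5]
        W = Y[:, 5:]
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

    return rhs_fn


# ---------------------------------------------------------------------------
# public integration entry points
# ---------------------------------------------------------------------------

def integrate_heun(
    x0: np.ndarray | None,
    proto: StimulusProtocol,
    p: ModelParams,
    dt: float = DEFAULT_DT,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Integrate one microcircuit under a stimulus protocol.

    ``x0`` is the initial 10-dim state (zero vector by default).  With
    ``noise`` given, a Gaussian value is drawn once per step from a
    generator seeded with ``seed`` and added to the targeted drive, so
    identical seeds give bit-identical trajectories.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    y0 = np.zeros(model.STATE_DIM) if x0 is None else np.asarray(x0, dtype=float)
    if y0.shape != (model.STATE_DIM,):
        raise ValueError(f"x0 must have shape (10,), got {y0.shape}")
    pe_arr, pi_arr = proto.drive_arrays(dt)
    n_steps = pe_arr.size
    rng = np.random.default_rng(seed)

    if noise is None:
        def drive(k):
            return pe_arr[k:k + 1], pi_arr[k:k + 1]
    else:
        def drive(k):
            eps = noise.mean + noise.sd * rng.standard_normal(1)
            if noise.target == "ext":
                return pe_arr[k:k + 1] + eps, pi_arr[k:k + 1]
            return pe_arr[k:k + 1], pi_arr[k:k + 1] + eps

    rhs_fn = make_rhs(p)
    ys, _ = heun_core(y0[None, :], n_steps, dt, drive, rhs_fn,
                      record="full", check_every=25)
    t = np.arange(n_steps + 1) * dt
    return Trajectory(
        t=t,
        y=ys[:, 0, :],
        p_ext=np.append(pe_arr, pe_arr[-1] if n_steps else 0.0),
        p_iin=np.append(pi_arr, pi_arr[-1] if n_steps else 0.0),
        params=p,
        dt=dt,
    )


def run_protocol(
    intensity: float,
    duration: float,
    p: ModelParams,
    dt: float = DEFAULT_DT,
    total_time: float = DEFAULT_TOTAL_TIME,
    settle_time: float = DEFAULT_SETTLE_TIME,
    x0: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Default experiment: settle, rectangular pulse, observe.

    A 5 s run with a 1 s settling period reproduces the standard
    stimulation protocol used for the response-behavior classification.
    """
    if intensity < 0 or duration < 0:
        raise ValueError("intensity and duration must be >= 0")
    proto = StimulusProtocol.rectangular(intensity, duration,
                                         settle_time=settle_time,
                                         total_time=total_time)
    return integrate_heun(x0, proto, p, dt=dt, noise=noise, seed=seed)
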