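"""Equilibrium structure and bifurcations of the canonical microcircuit.

The module provides two independent routes to the fixed-point curve:

* :func:`continue_branch` -- pseudo-arclength continuation of the
  five-dimensional steady-state system in ``(V, p_ext)`` with bordered
  Newton correction, eigenvalue-based stability and event detection
  (folds by turning points of ``p_ext``, Hopf points by a complex pair
  crossing the imaginary axis);
* :func:`equilibria_scan` / :func:`branch_sweep` -- the exact reduction
  of the equilibrium conditions to a scalar self-consistency relation in
  ``V_Py``, swept densely.  It serves as a brute-force cross-check of the
  continuation and as the workhorse for two-parameter (He, Hi) loci.

Fold points are typed by the eigenvalues at the fold itself: apart from
the vanishing eigenvalue, a saddle-node fold has the rest of the spectrum
in the left half plane (a stable and an unstable equilibrium collide),
while a saddle-saddle fold has at least one more unstable direction.
Hopf criticality is decided by simulation probing on the unstable side
(robust for a 10-dimensional system, where normal-form coefficients are
error prone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import model, simulate
from .model import ModelParams

__all__ = [
    "EquilibriumPoint",
    "BifurcationEvent",
    "FixedPointBranch",
    "Codim2Locus",
    "find_equilibria",
    "equilibria_scan",
    "branch_sweep",
    "continue_branch",
    "bistability_check",
    "trace_codim2",
    "nii_sweep",
]

#: an eigenvalue real part counts as nonzero above this (1e-6 after
#: nondimensionalizing time by tau_e = 10 ms)
EIG_TOL = 1e-4  # s^-1
#: imaginary part above this qualifies a pair as oscillatory
IMAG_TOL = 0.1  # s^-1
#: bifurcation events are localized in p_ext to this accuracy
EVENT_PTOL = 0.01  # s^-1


@dataclass(frozen=True)
class EquilibriumPoint:
    V: np.ndarray               # (5,) channel potentials, mV
    p_ext: float
    eigenvalues: np.ndarray     # (10,) complex
    stable: bool
    v_py: float


@dataclass(frozen=True)
class BifurcationEvent:
    kind: str                   # fold_sn | fold_ss | hopf_sub | hopf_super
    p_ext: float
    v_py: float
    method: str = ""


@dataclass
class FixedPointBranch:
    p_ext: np.ndarray           # (n,)
    V: np.ndarray               # (n, 5)
    v_py: np.ndarray            # (n,)
    stable: np.ndarray          # (n,) bool
    eigenvalues: np.ndarray     # (n, 10) complex
    events: list[BifurcationEvent] = field(default_factory=list)
    complete: bool = True

    def folds(self) -> list[BifurcationEvent]:
        return [e for e in self.events if e.kind.startswith("fold")]

    def hopfs(self) -> list[BifurcationEvent]:
        return [e for e in self.events if e.kind.startswith("hopf")]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "p_ext": self.p_ext,
            "V_Py": self.v_py,
            "stable": self.stable.astype(int),
            "max_re_eig": self.eigenvalues.real.max(axis=1),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def events_to_json(self) -> list[dict]:
        return [{"kind": e.kind, "p_ext": e.p_ext, "V_Py": e.v_py,
                 "method": e.method} for e in self.events]


# ---------------------------------------------------------------------------
# scalar reduction of the equilibrium conditions
# ---------------------------------------------------------------------------

def _solve_v5(V4: np.ndarray, p: ModelParams, iters: int = 64) -> np.ndarray:
    """Solve ``V5 = Hi tau_i (1-b2) N_II S(V4 - V5)`` by bisection.

    The right-hand side is strictly decreasing in V5, so the root is
    unique; bisection is robust for arbitrarily steep sigmoids (the map
    is not a contraction at large Hi).
    """
    a = p.arch
    if a.b2 >= 1.0:
        return np.zeros_like(V4)
    c = p.synapse.Hi * p.synapse.tau_i * (1.0 - a.b2) * p.gains.N_II
    lo = np.zeros_like(V4)
    hi = np.full_like(V4, c * 2.0 * p.sigmoid.e0 + 1e-9)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        above = c * model.sigmoid(V4 - mid, p.sigmoid) - mid > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def _downstream(x: np.ndarray, p: ModelParams):
    """Channels fixed by V_Py = x alone: (phi_p, V3, V4, V5)."""
    s, g = p.synapse, p.gains
    phi_p = model.sigmoid(x, p.sigmoid)
    V4 = s.He * s.tau_e * g.N_IP * phi_p
    V5 = _solve_v5(V4, p)
    phi_i = model.sigmoid(V4 - V5, p.sigmoid)
    V3 = s.Hi * s.tau_i * g.N_PI * phi_i
    return phi_p, V3, V4, V5


def branch_sweep(p: ModelParams, v_py_grid: np.ndarray):
    """Exact fixed-point curve parameterized by ``x = V_Py``.

    At equilibrium, every channel potential and the external drive are
    determined by ``x``; this returns ``(p_ext(x), V(x), valid)`` where
    ``valid`` marks grid points with a solution (for ``b1 = 1`` the branch
    only exists while ``V2`` stays inside the sigmoid's range).
    """
    x = np.asarray(v_py_grid, dtype=float)
    s, g, a = p.synapse, p.gains, p.arch
    he_te = s.He * s.tau_e
    phi_p, V3, V4, V5 = _downstream(x, p)
    V2 = x + V3
    valid = np.ones_like(x, dtype=bool)
    if a.b1 == 1.0:
        arg = V2 / (he_te * g.N_PE)
        valid = (arg > 1e-12) & (arg < 2.0 * p.sigmoid.e0 * (1 - 1e-12))
        safe = np.clip(arg, 1e-12, 2.0 * p.sigmoid.e0 * (1 - 1e-12))
        V1 = model.sigmoid_inverse(safe, p.sigmoid)
        p_ext = V1 / he_te - g.N_EP * phi_p
    elif a.b1 == 0.0:
        p_ext = V2 / he_te - g.N_PP * phi_p
        V1 = he_te * g.N_EP * phi_p
    else:
        # V2 = He te (b1 N_PE S(V1(pext)) + (1-b1)(N_PP phi_p + pext));
        # the right-hand side is strictly increasing in pext -> bisection
        lo = np.full_like(x, -2e4)
        hi = np.full_like(x, 2e4)
        for _ in range(90):
            mid = 0.5 * (lo + hi)
            v1m = he_te * (g.N_EP * phi_p + a.b1 * mid)
            v2m = he_te * (a.b1 * g.N_PE * model.sigmoid(v1m, p.sigmoid)
                           + (1.0 - a.b1) * (g.N_PP * phi_p + mid))
            below = v2m < V2
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        p_ext = 0.5 * (lo + hi)
        V1 = he_te * (g.N_EP * phi_p + a.b1 * p_ext)
    V = np.stack([V1, V2, V3, V4, V5], axis=-1)
    return p_ext, V, valid


def _saturation_boundary(p: ModelParams, target: float,
                         v_py_range: tuple[float, float]) -> float | None:
    """For ``b1 = 1``: the V_Py where ``V2(x) = x + V3(x)`` hits ``target``
    (the edge of the EIN sigmoid's range, where p_ext(x) diverges)."""
    def g(x):
        _, V3, _, _ = _downstream(np.array([x]), p)
        return x + V3[0] - target

    lo, hi = v_py_range
    if g(lo) * g(hi) > 0:
        return None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(lo) * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _eigs(V: np.ndarray, p: ModelParams) -> np.ndarray:
    return np.linalg.eigvals(model.jacobian(V, 0.0, p))


def _make_point(V: np.ndarray, p_ext: float, p: ModelParams) -> EquilibriumPoint:
    ev = _eigs(V, p)
    return EquilibriumPoint(V=np.asarray(V, float), p_ext=float(p_ext),
                            eigenvalues=ev, stable=bool(ev.real.max() < EIG_TOL),
                            v_py=float(V[1] - V[2]))


def equilibria_scan(
    p_ext: float,
    p: ModelParams,
    v_py_range: tuple[float, float] = (-20.0, 35.0),
    n_grid: int = 4001,
) -> list[EquilibriumPoint]:
    """Brute-force equilibria: dense scan of the scalar self-consistency
    relation ``p_ext(x) = p_ext`` with bisection refinement of each sign
    change.  Independent of the Newton/continuation machinery."""
    def crossings(xs, res):
        found = []
        for i in range(len(xs) - 1):
            a, b = res[i], res[i + 1]
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            if a == 0.0 or a * b < 0:
                lo, hi = xs[i], xs[i + 1]
                flo = a
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    fm = branch_sweep(p, np.array([mid]))[0][0] - p_ext
                    if flo * fm <= 0:
                        hi = mid
                    else:
                        lo, flo = mid, fm
                found.append(0.5 * (lo + hi))
        return found

    xs = np.linspace(*v_py_range, n_grid)
    px, _, valid = branch_sweep(p, xs)
    res = np.where(valid, px - p_ext, np.nan)
    roots = crossings(xs, res)
    # a root pair straddling a fold close to p_ext can hide between two
    # grid points; re-scan finely around near-zero local extrema
    for i in range(1, n_grid - 1):
        window = res[i - 1:i + 2]
        if not np.all(np.isfinite(window)):
            continue
        if np.abs(res[i]) == np.abs(window).min() and 0 < np.abs(res[i]) < 5.0 \
                and (res[i - 1] - res[i]) * (res[i + 1] - res[i]) > 0:
            xs_f = np.linspace(xs[i - 1], xs[i + 1], 801)
            px_f, _, valid_f = branch_sweep(p, xs_f)
            res_f = np.where(valid_f, px_f - p_ext, np.nan)
            roots.extend(crossings(xs_f, res_f))
    # for b1 = 1 the branch diverges logarithmically where V2 reaches the
    # edge of the EIN sigmoid's range; equilibria can hide arbitrarily
    # close to those asymptotes, so probe them on a log-distance grid
    if p.arch.b1 == 1.0 and p.gains.N_PE > 0:
        he_te = p.synapse.He * p.synapse.tau_e
        top = _saturation_boundary(p, he_te * p.gains.N_PE * 2 * p.sigmoid.e0,
                                   v_py_range)
        bottom = _saturation_boundary(p, 0.0, v_py_range)
        for xb, sign in ((top, -1.0), (bottom, +1.0)):
            if xb is None:
                continue
            ds = sign * np.logspace(-1, -13, 120)
            px_t, _, valid_t = branch_sweep(p, xb + ds)
            res_t = np.where(valid_t, px_t - p_ext, np.nan)
            roots.extend(crossings(xb + ds, res_t))

    pts = []
    for xr in sorted(roots):
        if pts and abs(xr - pts[-1].v_py) < 1e-8:
            continue
        _, V, _ = branch_sweep(p, np.array([xr]))
        pts.append(_make_point(V[0], p_ext, p))
    return pts


# ---------------------------------------------------------------------------
# Newton-based equilibria
# ---------------------------------------------------------------------------

def _residual(V: np.ndarray, p_ext: float, p: ModelParams) -> np.ndarray:
    return V - model.steady_state_map(V, p_ext, p)


def _residual_jac(V: np.ndarray, p: ModelParams) -> np.ndarray:
    H, tau = p.kernel_arrays()
    return np.eye(5) - (H * tau)[:, None] * model.input_jacobian(V, p)


def _newton(V0: np.ndarray, p_ext: float, p: ModelParams,
            tol: float = 1e-11, max_iter: int = 60) -> np.ndarray | None:
    V = np.asarray(V0, dtype=float).copy()
    r = _residual(V, p_ext, p)
    for _ in range(max_iter):
        nr = np.linalg.norm(r)
        if nr < tol:
            return V
        try:
            step = np.linalg.solve(_residual_jac(V, p), -r)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(10):  # damping: backtrack until the residual shrinks
            Vn = V + lam * step
            rn = _residual(Vn, p_ext, p)
            if np.linalg.norm(rn) < nr:
                V, r = Vn, rn
                break
            lam *= 0.5
        else:
            return None
    return V if np.linalg.norm(r) < 1e-8 else None


def _consistent_guess(x: float, p_ext: float, p: ModelParams) -> np.ndarray:
    """Initial V for Newton, exact in channels 3-5 given V_Py = x."""
    s, g, a = p.synapse, p.gains, p.arch
    phi_p, V3, V4, V5 = _downstream(np.array([x]), p)
    V1 = s.He * s.tau_e * (g.N_EP * phi_p[0] + a.b1 * p_ext)
    return np.array([V1, x + V3[0], V3[0], V4[0], V5[0]])


def find_equilibria(
    p_ext: float,
    p: ModelParams,
    n_starts: int = 25,
    seed: int | None = 0,
    dedup_tol: float = 1e-6,
) -> list[EquilibriumPoint]:
    """All equilibria at fixed drive, by damped Newton from multiple starts.

    Starts combine a deterministic grid of ``V_Py`` guesses over
    [-10, 16] mV with a few random perturbations; non-converged starts
    are dropped, duplicates merged.  A bounded sigmoid guarantees at
    least one equilibrium, so an empty result raises.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    starts = [_consistent_guess(x, p_ext, p)
              for x in np.linspace(-10.0, 16.0, n_starts)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        starts += list(rng.normal(0.0, 5.0, size=(max(3, n_starts // 5), 5)))
    found: list[np.ndarray] = []
    for V0 in starts:
        V = _newton(V0, p_ext, p)
        if V is None:
            continue
        if not any(np.linalg.norm(V - U) < dedup_tol for U in found):
            found.append(V)
    if not found:
        raise RuntimeError(
            f"no equilibrium found at p_ext={p_ext}; the bounded sigmoid "
            "guarantees one, so the start set is inadequate")
    return sorted((_make_point(V, p_ext, p) for V in found), key=lambda e: e.v_py)


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------

#: p_ext is weighted by this factor in the arclength metric so that mV and
#: s^-1 scales contribute comparably
P_WEIGHT = 0.05


def _G_and_jac(V: np.ndarray, p_ext: float, p: ModelParams):
    H, tau = p.kernel_arrays()
    G = V - H * tau * model.channel_inputs(V, p_ext, p)
    GV = _residual_jac(V, p)
    a = p.arch
    dup = np.array([a.b1, 1.0 - a.b1, 0.0, 0.0, 0.0])
    Gp = -(H * tau) * dup
    return G, GV, Gp


def _tangent(V, p_ext, p, prev: np.ndarray | None) -> np.ndarray:
    """Unit tangent (V', p') of the branch in the weighted metric."""
    _, GV, Gp = _G_and_jac(V, p_ext, p)
    A = np.zeros((6, 6))
    A[:5, :5] = GV
    A[:5, 5] = Gp
    if prev is None:
        A[5, :] = np.r_[np.zeros(5), 1.0]
    else:
        A[5, :] = prev * np.r_[np.ones(5), P_WEIGHT**2]
    b = np.zeros(6)
    b[5] = 1.0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # singular at a fold with p-normalization: fall back to nullspace
        M = np.hstack([GV, Gp[:, None]])
        _, _, vh = np.linalg.svd(M)
        t = vh[-1]
    norm = np.sqrt(np.sum(t[:5] ** 2) + (P_WEIGHT * t[5]) ** 2)
    t = t / norm
    if prev is not None:
        dot = np.sum(t[:5] * prev[:5]) + P_WEIGHT**2 * t[5] * prev[5]
        if dot < 0:
            t = -t
    return t


def _correct(z_pred: np.ndarray, t: np.ndarray, z_prev: np.ndarray, ds: float,
             p: ModelParams, tol: float = 1e-10, max_iter: int = 12):
    z = z_pred.copy()
    for _ in range(max_iter):
        G, GV, Gp = _G_and_jac(z[:5], z[5], p)
        arc = (np.sum(t[:5] * (z[:5] - z_prev[:5]))
               + P_WEIGHT**2 * t[5] * (z[5] - z_prev[5]) - ds)
        F = np.r_[G, arc]
        if np.linalg.norm(F) < tol:
            return z
        A = np.zeros((6, 6))
        A[:5, :5] = GV
        A[:5, 5] = Gp
        A[5, :5] = t[:5]
        A[5, 5] = P_WEIGHT**2 * t[5]
        try:
            z = z + np.linalg.solve(A, -F)
        except np.linalg.LinAlgError:
            return None
    return None


@dataclass
class StepControl:
    ds0: float = 0.2
    ds_min: float = 1e-5
    ds_max: float = 0.5
    grow: float = 1.3


def continue_branch(
    p_ext_range: tuple[float, float],
    p: ModelParams,
    step_ctl: StepControl | None = None,
    *,
    max_points: int = 4000,
    v_py_guard: tuple[float, float] = (-30.0, 45.0),
    classify_hopf: bool = True,
) -> FixedPointBranch:
    """Trace the fixed-point curve through ``p_ext_range``.

    Starts from the lowest-``V_Py`` equilibrium at the left end of the
    range and follows the branch by pseudo-arclength until the drive
    leaves the range.  Detected events (folds, Hopf points) are refined
    by bisection along the branch to ``EVENT_PTOL`` in ``p_ext``.
    """
    ctl = step_ctl or StepControl()
    p_lo, p_hi = sorted(p_ext_range)
    eqs = find_equilibria(p_lo, p)
    if not eqs:
        raise RuntimeError("no equilibrium at the start of the range")
    z = np.r_[eqs[0].V, p_lo]
    t = _tangent(z[:5], z[5], p, None)
    if t[5] < 0:
        t = -t

    pts_z: list[np.ndarray] = [z]
    pts_ev: list[np.ndarray] = [_eigs(z[:5], p)]
    events: list[BifurcationEvent] = []
    complete = True

    ds = ctl.ds0
    for _ in range(max_points):
        accepted = None
        while ds >= ctl.ds_min:
            z_new = _correct(z + ds * np.r_[t[:5], t[5]], t, z, ds, p)
            if z_new is not None:
                accepted = z_new
                break
            ds *= 0.5
        if accepted is None:
            warnings.warn("continuation step-size underflow; partial branch returned")
            complete = False
            break
        t_new = _tangent(accepted[:5], accepted[5], p, t)
        _detect_events(pts_z[-1], t, accepted, t_new, p, events, classify_hopf)
        pts_z.append(accepted)
        pts_ev.append(_eigs(accepted[:5], p))
        z, t = accepted, t_new
        ds = min(ds * ctl.grow, ctl.ds_max)
        vp = z[1] - z[2]
        if not (p_lo - 1e-9 <= z[5] <= p_hi + 1e-9) or not (
                v_py_guard[0] < vp < v_py_guard[1]):
            break
    else:
        warnings.warn("continuation reached max_points; partial branch returned")
        complete = False

    Z = np.array(pts_z)
    EV = np.array(pts_ev)
    return FixedPointBranch(
        p_ext=Z[:, 5], V=Z[:, :5], v_py=Z[:, 1] - Z[:, 2],
        stable=EV.real.max(axis=1) < EIG_TOL, eigenvalues=EV,
        events=events, complete=complete)


def _hopf_test(ev: np.ndarray) -> float:
    """Max real part over oscillatory eigenvalue pairs (-inf if none)."""
    osc = ev[np.abs(ev.imag) > IMAG_TOL]
    return float(osc.real.max()) if osc.size else -np.inf


def _bisect_on_branch(z_a, t_a, z_b, p, sign_fn, f_a):
    """Localize a sign change of ``sign_fn(z, t)`` between two branch
    points by arclength bisection; returns the refined point."""
    for _ in range(60):
        if abs(z_b[5] - z_a[5]) < EVENT_PTOL and (
                np.linalg.norm(z_b[:5] - z_a[:5]) < 1e-4):
            break
        ds = 0.5 * float(np.sum(t_a[:5] * (z_b[:5] - z_a[:5]))
                         + P_WEIGHT**2 * t_a[5] * (z_b[5] - z_a[5]))
        z_m = _correct(0.5 * (z_a + z_b), t_a, z_a, ds, p)
        if z_m is None:
            break
        t_m = _tangent(z_m[:5], z_m[5], p, t_a)
        f_m = sign_fn(z_m, t_m)
        if f_a * f_m <= 0:
            z_b = z_m
        else:
            z_a, t_a, f_a = z_m, t_m, f_m
    return 0.5 * (z_a + z_b)


def _fold_type(V: np.ndarray, p: ModelParams) -> str:
    """Type a fold by the spectrum at the fold point itself: ignoring the
    vanishing eigenvalue, any remaining unstable direction makes the two
    colliding equilibria both saddles."""
    ev = _eigs(V, p)
    i0 = np.argmin(np.abs(ev.real) + np.where(np.abs(ev.imag) > IMAG_TOL, 1e9, 0))
    rest = np.delete(ev, i0)
    return "fold_ss" if rest.real.max() > EIG_TOL else "fold_sn"


def _detect_events(z_a, t_a, z_b, t_b, p, events, classify_hopf_flag):
    # fold: the p-component of the tangent changes sign
    if t_a[5] * t_b[5] < 0:
        z_f = _bisect_on_branch(z_a, t_a, z_b, p,
                                lambda z, t: t[5], t_a[5])
        events.append(BifurcationEvent(
            kind=_fold_type(z_f[:5], p), p_ext=float(z_f[5]),
            v_py=float(z_f[1] - z_f[2]), method="tangent sign change"))
    # Hopf: an oscillatory pair crosses the imaginary axis
    h_a = _hopf_test(_eigs(z_a[:5], p))
    h_b = _hopf_test(_eigs(z_b[:5], p))
    if np.isfinite(h_a) and np.isfinite(h_b) and h_a * h_b < 0:
        z_h = _bisect_on_branch(z_a, t_a, z_b, p,
                                lambda z, t: _hopf_test(_eigs(z[:5], p)), h_a)
        # reject discontinuous sign flips (a real pair merging into a
        # complex one near a fold): a genuine Hopf has its oscillatory
        # pair *on* the imaginary axis at the refined point
        ev_h = _eigs(z_h[:5], p)
        h_here = _hopf_test(ev_h)
        osc = ev_h[np.abs(ev_h.imag) > IMAG_TOL]
        if not np.isfinite(h_here) or abs(h_here) > 1.0 or osc.size == 0:
            return
        kind = "hopf_sub"
        method = "eigenvalue crossing"
        if classify_hopf_flag:
            kind, method = _hopf_criticality(z_h, z_a, z_b, h_a, p)
        events.append(BifurcationEvent(
            kind=kind, p_ext=float(z_h[5]),
            v_py=float(z_h[1] - z_h[2]), method=method))


def _hopf_criticality(z_h, z_a, z_b, h_a, p) -> tuple[str, str]:
    """Sub/supercritical by simulation probing just on the unstable side.

    A supercritical Hopf leaves a small stable limit cycle next to the
    unstable focus; a subcritical one repels trajectories to a distant
    attractor.
    """
    # unstable side: pick the bracket endpoint whose pair has Re > 0
    z_u = z_a if h_a > 0 else z_b
    # probe the equilibrium ~2 s^-1 beyond the Hopf on the unstable side
    d = z_u - z_h
    if abs(d[5]) > 1e-3:
        d = d * min(2.0 / abs(d[5]), 3.0)
    z_p = z_h + d
    V = _newton(z_p[:5], float(z_p[5]), p)
    if V is not None and _hopf_test(_eigs(V, p)) < 0:
        # landed on the stable side of the crossing; push further out
        z_p = z_h + 2.0 * d
        V = _newton(z_p[:5], float(z_p[5]), p)
    if V is None:
        V = z_p[:5]
    # growth rates next to the crossing are small (<~0.3 s^-1), so the
    # probe needs a long horizon before sub/super distinguish themselves
    y0 = model.embed(V)
    y0[1] += 0.05  # small kick off the focus
    rhs_fn = simulate.make_rhs(p)
    pe = np.array([float(z_p[5])])
    pi = np.zeros(1)
    vpy, _ = simulate.heun_core(y0[None, :], 20000, 1e-3,
                                lambda k: (pe, pi), rhs_fn, record="vpy")
    tail = vpy[18000:, 0]
    dist = np.abs(tail - (V[1] - V[2]))
    if dist.mean() > 2.0:
        return "hopf_sub", "simulation probe (escape to distant attractor)"
    return "hopf_super", "simulation probe (bounded local cycle)"


# ---------------------------------------------------------------------------
# attractor counting
# ---------------------------------------------------------------------------

def bistability_check(p: ModelParams, p_ext: float = 0.0) -> str:
    """Count coexisting attractors at fixed drive.

    Returns ``"monostable"``, ``"bistable_nodes"`` (two stable equilibria)
    or ``"bistable_with_limit_cycle"`` (one stable equilibrium plus a
    sustained oscillation found by simulating from a perturbed high
    state).
    """
    eqs = find_equilibria(p_ext, p)
    n_stable = sum(e.stable for e in eqs)
    if n_stable >= 2:
        return "bistable_nodes"
    if len(eqs) >= 2:
        # probe for a stable limit cycle around the upper (unstable) branch
        top = eqs[-1]
        y0 = model.embed(top.V)
        y0[1] += 0.1
        vpy, _ = simulate.heun_core(
            y0[None, :], 6000, 1e-3,
            lambda k: (np.array([p_ext]), np.zeros(1)),
            simulate.make_rhs(p), record="vpy")
        tail = vpy[5000:, 0]
        stable_eq = next(e for e in eqs if e.stable)
        converged = np.all(np.abs(tail - stable_eq.v_py) < 0.1)
        if not converged and np.ptp(tail) > OSC_PTP_LC:
            return "bistable_with_limit_cycle"
    return "monostable"


OSC_PTP_LC = 0.5  # mV; sustained oscillation amplitude for limit-cycle calls


# ---------------------------------------------------------------------------
# two-parameter loci
# ---------------------------------------------------------------------------

@dataclass
class Codim2Locus:
    """Curve in the (He, Hi) plane where a bifurcation sits at p_ext = 0."""

    branch_type: str            # "fold_upper" | "fold_lower" | "hopf"
    He: np.ndarray
    Hi: np.ndarray
    v_py: np.ndarray
    kinds: list[str]            # per-point classification
    degenerate: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"He": self.He, "Hi": self.Hi,
                             "V_Py": self.v_py, "kind": self.kinds})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _folds_of_sweep(p: ModelParams, xs: np.ndarray):
    """Fold candidates: local extrema of p_ext(x) along the branch."""
    px, _, valid = branch_sweep(p, xs)
    px = np.where(valid, px, np.nan)
    dp = np.diff(px)
    sgn = np.sign(dp)
    out = []
    for i in range(1, len(sgn)):
        if np.isfinite(sgn[i - 1]) and np.isfinite(sgn[i]) and sgn[i - 1] * sgn[i] < 0:
            out.append((xs[i], "max" if sgn[i - 1] > 0 else "min", i))
    return out, px


def _refine_fold(p: ModelParams, lo: float, hi: float, kind: str) -> tuple[float, float]:
    """Ternary search for the extremum of p_ext(x) in [lo, hi]."""
    for _ in range(48):
        m1, m2 = lo + (hi - lo) / 3, hi - (hi - lo) / 3
        pm = branch_sweep(p, np.array([m1, m2]))[0]
        if (pm[0] > pm[1]) == (kind == "max"):
            hi = m2
        else:
            lo = m1
    xf = 0.5 * (lo + hi)
    return xf, float(branch_sweep(p, np.array([xf]))[0][0])


def fold_location(p: ModelParams, which: str,
                  v_py_range: tuple[float, float] = (-15.0, 40.0),
                  n_grid: int = 3001,
                  x_near: float | None = None):
    """Locate a fold of the equilibrium curve: ``(x_fold, p_fold)``.

    ``which`` is "upper"/"lower" (largest/smallest V_Py extremum); with
    ``x_near`` given, the extremum closest to that V_Py is tracked
    instead, which keeps two-parameter tracing on one fold sheet.
    Returns None when the branch is monotone (no fold).
    """
    if x_near is not None:
        # local window around the tracked fold keeps tracing cheap
        v_py_range = (x_near - 4.0, x_near + 4.0)
        n_grid = 801
    xs = np.linspace(*v_py_range, n_grid)
    cands, _ = _folds_of_sweep(p, xs)
    if not cands:
        return None
    if x_near is not None:
        x0, kind, i = min(cands, key=lambda c: abs(c[0] - x_near))
    elif which == "upper":
        x0, kind, i = max(cands, key=lambda c: c[0])
    else:
        x0, kind, i = min(cands, key=lambda c: c[0])
    xf, pf = _refine_fold(p, xs[max(i - 2, 0)], xs[min(i + 2, n_grid - 1)], kind)
    return xf, pf


def trace_codim2(
    branch_type: str,
    Hi_values: Sequence[float],
    p: ModelParams,
    He_bracket: tuple[float, float] = (0.8, 8.0),
    *,
    refine_degenerate: bool = True,
) -> Codim2Locus:
    """Trace a fold locus at ``p_ext = 0`` through the (He, Hi) plane.

    For each Hi the He value placing the requested fold exactly at zero
    drive is found by bisection; the fold is followed between Hi values
    by proximity in ``V_Py`` so the locus stays on one sheet.  Each point
    carries the local fold type; type changes along the locus (the
    saddle-node to saddle-saddle split where a Hopf branch detaches) are
    flagged and refined in Hi.
    """
    if branch_type not in ("fold_upper", "fold_lower"):
        raise ValueError("branch_type must be 'fold_upper' or 'fold_lower'")
    which = branch_type.split("_")[1]
    He_list, Hi_list, vp_list, kinds = [], [], [], []
    degenerate: list[dict] = []
    x_prev: float | None = None
    He_prev: float | None = None

    def locus_point(Hi: float, x_ref, He_lo, He_hi):
        def f(He):
            q = p.replace(He=He, Hi=Hi)
            r = fold_location(q, which, x_near=x_ref)
            return (r[1], r[0]) if r else (None, None)

        # scan for a sign-change sub-bracket (folds need not exist
        # everywhere in the He window)
        hes = np.linspace(He_lo, He_hi, 13)
        vals = [f(he)[0] for he in hes]
        lo = hi = plo = None
        for (h1, v1), (h2, v2) in zip(zip(hes, vals), zip(hes[1:], vals[1:])):
            if v1 is not None and v2 is not None and v1 * v2 <= 0:
                lo, hi, plo = h1, h2, v1
                break
        if lo is None:
            return None
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            pm, _ = f(mid)
            if pm is None:
                return None
            if plo * pm <= 0:
                hi = mid
            else:
                lo, plo = mid, pm
        He_root = 0.5 * (lo + hi)
        pf, xf = f(He_root)
        q = p.replace(He=He_root, Hi=Hi)
        _, V, _ = branch_sweep(q, np.array([xf]))
        return He_root, xf, _fold_type(V[0], q)

    for Hi in Hi_values:
        if He_prev is None:
            res = locus_point(Hi, None, *He_bracket)
        else:
            res = (locus_point(Hi, x_prev, max(He_bracket[0], He_prev - 1.0),
                               min(He_bracket[1], He_prev + 1.0))
                   or locus_point(Hi, x_prev, *He_bracket))
        if res is None:
            warnings.warn(f"{branch_type} locus lost at Hi={Hi}; truncating")
            break
        He_root, xf, kind = res
        if kinds and kind != kinds[-1] and refine_degenerate:
            lo_hi, hi_hi = Hi_list[-1], Hi
            k_lo = kinds[-1]
            x_ref_l, he_ref = x_prev, He_prev
            for _ in range(25):
                if hi_hi - lo_hi < 0.02:
                    break
                mid = 0.5 * (lo_hi + hi_hi)
                r = locus_point(mid, x_ref_l, max(He_bracket[0], he_ref - 1.0),
                                min(He_bracket[1], he_ref + 1.0))
                if r is None:
                    break
                if r[2] == k_lo:
                    lo_hi, he_ref, x_ref_l = mid, r[0], r[1]
                else:
                    hi_hi = mid
            degenerate.append({"Hi": 0.5 * (lo_hi + hi_hi),
                               "from": kinds[-1], "to": kind})
        He_list.append(He_root)
        Hi_list.append(Hi)
        vp_list.append(xf)
        kinds.append(kind)
        He_prev, x_prev = He_root, xf

    return Codim2Locus(
        branch_type=branch_type,
        He=np.array(He_list), Hi=np.array(Hi_list), v_py=np.array(vp_list),
        kinds=kinds, degenerate=degenerate,
        metadata={"base_params": model.params_to_dict(p)})


def nii_sweep(
    nii_values: Sequence[float],
    p: ModelParams,
    p_ext_range: tuple[float, float] = (-150.0, 250.0),
) -> list[tuple[float, FixedPointBranch]]:
    """Branches and events of the disinhibited model as the recurrent IIN
    self-feedback ``N_II`` is increased; requires ``b1 = 0, b2 = 0``."""
    if p.arch.b1 != 0.0 or p.arch.b2 != 0.0:
        raise ValueError("nii_sweep requires the disinhibited architecture "
                         "(b1 = 0, b2 = 0)")
    out = []
    for nii in nii_values:
        q = p.replace(N_II=float(nii))
        out.append((float(nii), continue_branch(p_ext_range, q,
                                                classify_hopf=False)))
    return out
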