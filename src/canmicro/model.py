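"""Core definition of the canonical-microcircuit neural mass model.

A single microcircuit couples three neural populations -- pyramidal cells
(Py), excitatory interneurons (EIN) and inhibitory interneurons (IIN) --
through alpha-function synaptic kernels and a logistic firing-rate
activation.  Each of the five synaptic channels obeys a critically damped
second-order kernel, so the full circuit is a ten-dimensional ODE in the
channel potentials ``V1..V5`` and their time derivatives ``W1..W5``.

Two architectural weights select the feedback topology:

* ``b1`` blends indirect excitatory feedback through the EIN (``b1 = 1``,
  three populations) into direct Py self-feedback (``b1 = 0``, two
  populations); it also routes the external drive to the EIN or the Py.
* ``b2`` switches the recurrent IIN self-feedback off (``b2 = 1``) or on
  (``b2 = 0``, disinhibition).

Units are mV, s and s^-1 throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "SigmoidParams",
    "SynapseParams",
    "ConnectivityGains",
    "ArchitectureParams",
    "ModelParams",
    "CircuitState",
    "STATE_DIM",
    "sigmoid",
    "sigmoid_slope",
    "sigmoid_inverse",
    "channel_inputs",
    "rhs",
    "steady_state_map",
    "jacobian",
    "embed",
    "v_py",
    "params_to_dict",
    "params_from_dict",
    "load_params",
    "save_params",
]

STATE_DIM = 10

#: clamp on the sigmoid exponent argument; avoids floating overflow for
#: extreme membrane potentials without affecting any physical value
_EXP_CLAMP = 500.0

# flat serialization keys, in canonical order
_PARAM_KEYS = (
    "He", "Hi", "tau_e", "tau_i",
    "N_EP", "N_PE", "N_IP", "N_PI", "N_PP", "N_II",
    "e0", "r", "v0", "b1", "b2",
)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic activation: ``e0`` is half the maximum rate (s^-1), ``r``
    the maximum slope (mV^-1) and ``v0`` the half-activation potential (mV)."""

    e0: float = 2.5
    r: float = 0.56
    v0: float = 6.0

    def __post_init__(self) -> None:
        _require(self.e0 > 0, f"e0 must be > 0, got {self.e0}")
        _require(self.r > 0, f"r must be > 0, got {self.r}")


@dataclass(frozen=True)
class SynapseParams:
    """Alpha-kernel gains (mV) and time constants (s) of the excitatory
    and inhibitory synapses."""

    He: float = 3.25
    Hi: float = 22.0
    tau_e: float = 0.010
    tau_i: float = 0.020

    def __post_init__(self) -> None:
        for name in ("He", "Hi", "tau_e", "tau_i"):
            _require(getattr(self, name) > 0,
                     f"{name} must be > 0, got {getattr(self, name)}")


def _default_gains() -> tuple[float, ...]:
    n_ep = 135.0
    return (n_ep, 0.8 * n_ep, 0.25 * n_ep, 0.25 * n_ep, 113.4, 33.25)


@dataclass(frozen=True)
class ConnectivityGains:
    """Dimensionless inter-population gains ``N_ab`` (source ``b`` to
    target ``a``).  ``N_PP`` and ``N_II`` only act in the two-population
    architectures (``b1 < 1`` resp. ``b2 < 1``)."""

    N_EP: float = 135.0
    N_PE: float = 0.8 * 135.0
    N_IP: float = 0.25 * 135.0
    N_PI: float = 0.25 * 135.0
    N_PP: float = 113.4
    N_II: float = 33.25

    def __post_init__(self) -> None:
        for name in ("N_EP", "N_PE", "N_IP", "N_PI", "N_PP", "N_II"):
            _require(getattr(self, name) >= 0,
                     f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ArchitectureParams:
    """Topology weights; both constrained to [0, 1].

    ``(b1, b2) = (1, 1)``: three-population model.
    ``(0, 1)``: two-population model.
    ``(0, 0)``: two-population model with disinhibition.
    """

    b1: float = 1.0
    b2: float = 1.0

    def __post_init__(self) -> None:
        _require(0.0 <= self.b1 <= 1.0, f"b1 must be in [0, 1], got {self.b1}")
        _require(0.0 <= self.b2 <= 1.0, f"b2 must be in [0, 1], got {self.b2}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one canonical microcircuit."""

    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    gains: ConnectivityGains = field(default_factory=ConnectivityGains)
    arch: ArchitectureParams = field(default_factory=ArchitectureParams)

    # ---- constructors -------------------------------------------------
    @classmethod
    def table1(cls) -> "ModelParams":
        """Standard parameter set (three-population architecture)."""
        return cls()

    @classmethod
    def two_population(cls) -> "ModelParams":
        return cls(arch=ArchitectureParams(b1=0.0, b2=1.0))

    @classmethod
    def two_population_disinhibited(cls) -> "ModelParams":
        return cls(arch=ArchitectureParams(b1=0.0, b2=0.0))

    def replace(self, **flat: float) -> "ModelParams":
        """Return a copy with flat symbol-name overrides (``He=3.0`` ...)."""
        d = params_to_dict(self)
        for k, v in flat.items():
            if k not in d:
                raise KeyError(f"unknown parameter {k!r}; valid: {_PARAM_KEYS}")
            d[k] = float(v)
        return params_from_dict(d)

    # ---- precomputed per-channel kernel arrays ------------------------
    def kernel_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(H, tau) of shape (5,): channels 1, 2, 4 are excitatory and
        3, 5 inhibitory."""
        s = self.synapse
        H = np.array([s.He, s.He, s.Hi, s.He, s.Hi])
        tau = np.array([s.tau_e, s.tau_e, s.tau_i, s.tau_e, s.tau_i])
        return H, tau


@dataclass
class CircuitState:
    """Convenience wrapper for the 10-dimensional state vector.

    The serialization order is ``(V1..V5, W1..W5)``.  ``V_Py = V2 - V3``
    is the observable output of the circuit, ``V_E = V1`` and
    ``V_I = V4 - V5`` the interneuron potentials.
    """

    V: np.ndarray
    W: np.ndarray

    @classmethod
    def zeros(cls) -> "CircuitState":
        return cls(V=np.zeros(5), W=np.zeros(5))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CircuitState":
        y = np.asarray(y, dtype=float)
        if y.shape != (STATE_DIM,):
            raise ValueError(f"state vector must have shape (10,), got {y.shape}")
        return cls(V=y[:5].copy(), W=y[5:].copy())

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.V, self.W])

    @property
    def v_py(self) -> float:
        return float(self.V[1] - self.V[2])

    @property
    def v_e(self) -> float:
        return float(self.V[0])

    @property
    def v_i(self) -> float:
        return float(self.V[3] - self.V[4])


# ---------------------------------------------------------------------------
# activation function
# ---------------------------------------------------------------------------

def sigmoid(V, sp: SigmoidParams = SigmoidParams()):
    """Mean firing rate (s^-1) for membrane potential ``V`` (mV).

    ``S(V) = 2 e0 / (1 + exp(r (v0 - V)))``; strictly increasing and
    bounded in ``(0, 2 e0)``.
    """
    arg = np.clip(sp.r * (sp.v0 - np.asarray(V, dtype=float)), -_EXP_CLAMP, _EXP_CLAMP)
    return 2.0 * sp.e0 / (1.0 + np.exp(arg))


def sigmoid_slope(V, sp: SigmoidParams = SigmoidParams()):
    """dS/dV = r S (1 - S / (2 e0))."""
    s = sigmoid(V, sp)
    return sp.r * s * (1.0 - s / (2.0 * sp.e0))


def sigmoid_inverse(phi, sp: SigmoidParams = SigmoidParams()):
    """Membrane potential at which the activation outputs ``phi``;
    defined for ``phi`` strictly inside ``(0, 2 e0)``."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi >= 2 * sp.e0):
        raise ValueError("sigmoid_inverse requires 0 < phi < 2*e0")
    return sp.v0 - np.log(2.0 * sp.e0 / phi - 1.0) / sp.r


# ---------------------------------------------------------------------------
# right-hand side and steady state
# ---------------------------------------------------------------------------

def channel_inputs(V, p_ext, p: ModelParams, p_iin=0.0):
    """Total firing-rate input ``u_k`` to each synaptic channel.

    ``V`` has shape (..., 5); ``p_ext`` / ``p_iin`` are scalars or arrays
    broadcastable to the leading shape.  Returns shape (..., 5).
    """
    V = np.asarray(V, dtype=float)
    g, a, sp = p.gains, p.arch, p.sigmoid
    phi_p = sigmoid(V[..., 1] - V[..., 2], sp)
    phi_e = sigmoid(V[..., 0], sp)
    phi_i = sigmoid(V[..., 3] - V[..., 4], sp)
    p_ext = np.asarray(p_ext, dtype=float)
    p_iin = np.asarray(p_iin, dtype=float)
    u = np.empty(V.shape, dtype=float)
    u[..., 0] = g.N_EP * phi_p + a.b1 * p_ext
    u[..., 1] = (a.b1 * g.N_PE * phi_e
                 + (1.0 - a.b1) * g.N_PP * phi_p
                 + (1.0 - a.b1) * p_ext)
    u[..., 2] = g.N_PI * phi_i
    u[..., 3] = g.N_IP * phi_p + p_iin
    u[..., 4] = (1.0 - a.b2) * g.N_II * phi_i
    return u


def rhs(y, p_ext, p: ModelParams, p_iin=0.0):
    """Time derivative of the 10-dimensional state.

    Each channel with kernel ``(H, tau)`` and input ``u`` obeys
    ``V' = W``, ``W' = (H/tau) u - (2/tau) W - V/tau^2``.  ``y`` has shape
    (..., 10).  Raises on non-finite input (numerical blow-up guard).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to rhs")
    H, tau = p.kernel_arrays()
    V, W = y[..., :5], y[..., 5:]
    u = channel_inputs(V, p_ext, p, p_iin)
    dW = (H / tau) * u - (2.0 / tau) * W - V / tau**2
    return np.concatenate([W, dW], axis=-1)


def steady_state_map(V, p_ext, p: ModelParams, p_iin=0.0):
    """Algebraic fixed-point map ``V -> H tau u(V)``.

    At steady state each second-order kernel reduces to multiplication by
    ``H tau``, so fixed points of this five-dimensional map are exactly
    the equilibria of :func:`rhs`.
    """
    H, tau = p.kernel_arrays()
    return H * tau * channel_inputs(V, p_ext, p, p_iin)


def embed(V) -> np.ndarray:
    """Lift five potentials to the 10-dim state with zero derivatives."""
    V = np.asarray(V, dtype=float)
    return np.concatenate([V, np.zeros_like(V)], axis=-1)


def v_py(y) -> np.ndarray:
    """Pyramidal-cell membrane potential ``V2 - V3`` from state (..., 10)."""
    y = np.asarray(y)
    return y[..., 1] - y[..., 2]


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------

def input_jacobian(V, p: ModelParams) -> np.ndarray:
    """``du_k/dV_j`` (5 x 5) of :func:`channel_inputs` at potentials V."""
    V = np.asarray(V, dtype=float)
    g, a, sp = p.gains, p.arch, p.sigmoid
    d_p = sigmoid_slope(V[1] - V[2], sp)
    d_e = sigmoid_slope(V[0], sp)
    d_i = sigmoid_slope(V[3] - V[4], sp)
    dU = np.zeros((5, 5))
    dU[0, 1], dU[0, 2] = g.N_EP * d_p, -g.N_EP * d_p
    dU[1, 0] = a.b1 * g.N_PE * d_e
    dU[1, 1] = (1.0 - a.b1) * g.N_PP * d_p
    dU[1, 2] = -(1.0 - a.b1) * g.N_PP * d_p
    dU[2, 3], dU[2, 4] = g.N_PI * d_i, -g.N_PI * d_i
    dU[3, 1], dU[3, 2] = g.N_IP * d_p, -g.N_IP * d_p
    dU[4, 3] = (1.0 - a.b2) * g.N_II * d_i
    dU[4, 4] = -(1.0 - a.b2) * g.N_II * d_i
    return dU


def jacobian(y, p_ext, p: ModelParams, p_iin=0.0) -> np.ndarray:
    """Analytic 10 x 10 Jacobian of :func:`rhs` at state ``y``.

    The drive enters additively, so the Jacobian does not depend on
    ``p_ext``/``p_iin``; they are accepted for interface symmetry.
    """
    y = np.asarray(y, dtype=float)
    if y.shape == (5,):
        V = y
    elif y.shape == (STATE_DIM,):
        V = y[:5]
    else:
        raise ValueError(f"expected state of shape (5,) or (10,), got {y.shape}")
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite state passed to jacobian")
    H, tau = p.kernel_arrays()
    A = (H / tau)[:, None] * input_jacobian(V, p) - np.diag(1.0 / tau**2)
    J = np.zeros((STATE_DIM, STATE_DIM))
    J[:5, 5:] = np.eye(5)
    J[5:, :5] = A
    J[5:, 5:] = -np.diag(2.0 / tau)
    return J


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def params_to_dict(p: ModelParams) -> dict:
    s, g, a, sg = p.synapse, p.gains, p.arch, p.sigmoid
    return {
        "He": s.He, "Hi": s.Hi, "tau_e": s.tau_e, "tau_i": s.tau_i,
        "N_EP": g.N_EP, "N_PE": g.N_PE, "N_IP": g.N_IP, "N_PI": g.N_PI,
        "N_PP": g.N_PP, "N_II": g.N_II,
        "e0": sg.e0, "r": sg.r, "v0": sg.v0,
        "b1": a.b1, "b2": a.b2,
    }


def params_from_dict(d: Mapping[str, float]) -> ModelParams:
    """Build :class:`ModelParams` from flat symbol keys; unknown keys and
    invariant violations raise ``ValueError`` naming the offending key."""
    unknown = set(d) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    full = params_to_dict(ModelParams())
    full.update({k: float(v) for k, v in d.items()})
    return ModelParams(
        sigmoid=SigmoidParams(e0=full["e0"], r=full["r"], v0=full["v0"]),
        synapse=SynapseParams(He=full["He"], Hi=full["Hi"],
                              tau_e=full["tau_e"], tau_i=full["tau_i"]),
        gains=ConnectivityGains(N_EP=full["N_EP"], N_PE=full["N_PE"],
                                N_IP=full["N_IP"], N_PI=full["N_PI"],
                                N_PP=full["N_PP"], N_II=full["N_II"]),
        arch=ArchitectureParams(b1=full["b1"], b2=full["b2"]),
    )


def save_params(p: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p), fh, sort_keys=False)


def load_params(path) -> ModelParams:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return params_from_dict(d)
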