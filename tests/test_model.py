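"""Unit tests of the model core: activation, dynamics, Jacobian, I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from canmicro import model
from canmicro.model import (
    ArchitectureParams,
    CircuitState,
    ModelParams,
    SigmoidParams,
    embed,
    jacobian,
    params_from_dict,
    params_to_dict,
    rhs,
    sigmoid,
    sigmoid_inverse,
    sigmoid_slope,
    steady_state_map,
)


class TestSigmoid:
    def test_half_maximum_at_v0(self):
        assert sigmoid(6.0) == pytest.approx(2.5)

    def test_firing_threshold_fraction(self):
        # at the 4 mV firing threshold roughly a quarter of the 5 s^-1
        # maximum rate is reached
        s = sigmoid(4.0)
        assert s == pytest.approx(1.2301, abs=1e-3)
        assert 0.24 < s / 5.0 < 0.26

    def test_saturation(self):
        assert sigmoid(1e4) == pytest.approx(5.0)
        assert sigmoid(-1e4) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-60, 60), st.floats(-60, 60))
    def test_monotone_and_bounded(self, a, b):
        sa, sb = sigmoid(a), sigmoid(b)
        assert 0.0 < sa < 5.0
        if a + 1e-9 < b:
            assert sa < sb

    @given(st.floats(-15, 15))
    def test_slope_matches_finite_difference(self, v):
        # central difference with a step large enough to dominate the
        # floating-point cancellation in S(v+h) - S(v-h)
        h = 1e-5
        fd = (sigmoid(v + h) - sigmoid(v - h)) / (2 * h)
        assert sigmoid_slope(v) == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_inverse_round_trip(self):
        for v in [-5.0, 0.0, 6.0, 12.0]:
            assert sigmoid_inverse(sigmoid(v)) == pytest.approx(v, abs=1e-9)

    def test_inverse_domain(self):
        with pytest.raises(ValueError):
            sigmoid_inverse(5.0)

    def test_extreme_potential_no_overflow(self):
        # the exponent clamp keeps the activation finite at any potential
        assert np.isfinite(sigmoid(-1e9))

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="e0"):
            SigmoidParams(e0=-1.0)


class TestRhs:
    def test_zero_state_has_nonzero_derivative(self, table1):
        # S(0) > 0 feeds channels with nonzero gains: the origin is not
        # the resting state
        dy = rhs(np.zeros(10), 0.0, table1)
        assert np.abs(dy).max() > 0

    def test_zero_at_equilibrium(self, table1):
        from canmicro import find_equilibria
        for eq in find_equilibria(0.0, table1):
            assert np.abs(rhs(embed(eq.V), 0.0, table1)).max() < 1e-7

    def test_single_channel_closed_form(self, zero_gain_params):
        # with all gains zero and b1 = 1 only channel 1 is driven; its
        # steady state is He * tau_e * p_ext
        V_star = steady_state_map(np.zeros(5), 100.0, zero_gain_params)
        assert V_star[0] == pytest.approx(3.25)
        assert np.all(V_star[1:] == 0.0)

    def test_nonfinite_state_rejected(self, table1):
        y = np.zeros(10)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(y, 0.0, table1)

    def test_map_rhs_identity(self, table1, rng):
        # W' = (steady_state_map(V) - V) / tau^2 when W = 0, so the map's
        # fixed points and the equilibria of rhs coincide exactly
        _, tau = table1.kernel_arrays()
        for _ in range(5):
            V = rng.normal(0, 5, 5)
            dy = rhs(embed(V), 7.0, table1, p_iin=2.0)
            m = steady_state_map(V, 7.0, table1, p_iin=2.0)
            assert dy[5:] == pytest.approx((m - V) / tau**2, rel=1e-12)

    def test_b1_weighted_terms_vanish(self, table1, rng):
        # at b1 = 1 the direct-feedback terms are absent: N_PP must not
        # influence the dynamics
        y = rng.normal(0, 3, 10)
        alt = table1.replace(N_PP=999.0)
        assert np.array_equal(rhs(y, 50.0, table1), rhs(y, 50.0, alt))


class TestJacobian:
    @pytest.mark.parametrize("b1,b2", [(1.0, 1.0), (0.0, 1.0), (0.0, 0.0), (0.4, 0.7)])
    def test_matches_finite_differences(self, b1, b2, rng):
        p = ModelParams(arch=ArchitectureParams(b1=b1, b2=b2))
        for _ in range(5):
            y = rng.normal(0, 5, 10)
            J = jacobian(y, 3.0, p)
            Jfd = np.empty((10, 10))
            for j in range(10):
                e = np.zeros(10)
                e[j] = 1e-6
                Jfd[:, j] = (rhs(y + e, 3.0, p) - rhs(y - e, 3.0, p)) / 2e-6
            assert np.abs(J - Jfd).max() / np.abs(Jfd).max() < 1e-6

    def test_zero_gain_block_eigenvalues(self, zero_gain_params):
        # decoupled critically damped channels: double eigenvalue -1/tau
        ev = np.sort(np.linalg.eigvals(jacobian(np.zeros(10), 0.0,
                                                zero_gain_params)).real)
        tau_vals = [0.01] * 3 + [0.02] * 2
        expect = np.sort(np.repeat([-1.0 / t for t in tau_vals], 2))
        assert ev == pytest.approx(expect, rel=1e-8)

    def test_low_state_damped_oscillation(self, table1):
        # the resting state's leading eigenvalues are a stable complex
        # pair: perturbations decay as a damped oscillation
        from canmicro import find_equilibria
        low = find_equilibria(0.0, table1)[0]
        lead = low.eigenvalues[np.argmax(low.eigenvalues.real)]
        assert lead.real < 0
        assert abs(lead.imag) > 1.0


class TestContinuityInB1:
    def test_equilibrium_vpy_continuous(self):
        # the resting V_Py at zero drive varies continuously along the
        # architectural interpolation b1 in [0, 1]
        from canmicro import find_equilibria
        vals = []
        for b1 in np.linspace(0.0, 1.0, 21):
            p = ModelParams(arch=ArchitectureParams(b1=b1, b2=1.0))
            vals.append(find_equilibria(0.0, p)[0].v_py)
        steps = np.abs(np.diff(vals))
        assert steps.max() < 0.1


class TestSerialization:
    def test_round_trip(self, tmp_path, table1):
        path = tmp_path / "params.yaml"
        model.save_params(table1.replace(He=2.9, b1=0.3), path)
        q = model.load_params(path)
        assert params_to_dict(q) == params_to_dict(table1.replace(He=2.9, b1=0.3))

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            params_from_dict({"bogus": 1.0})

    def test_invalid_value_names_field(self):
        with pytest.raises(ValueError, match="tau_e"):
            params_from_dict({"tau_e": -0.01})

    def test_default_gain_ratios(self, table1):
        g = table1.gains
        assert g.N_PE == pytest.approx(0.8 * g.N_EP)
        assert g.N_IP == g.N_PI == pytest.approx(0.25 * g.N_EP)

    def test_circuit_state_round_trip(self, rng):
        y = rng.normal(size=10)
        st_ = CircuitState.from_vector(y)
        assert np.array_equal(st_.as_vector(), y)
        assert st_.v_py == pytest.approx(y[1] - y[2])
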