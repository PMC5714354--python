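"""Tests of equilibrium finding, continuation and two-parameter tracing."""

import numpy as np
import pytest

from canmicro import (
    ModelParams,
    bistability_check,
    continue_branch,
    equilibria_scan,
    find_equilibria,
    nii_sweep,
    trace_codim2,
)
from canmicro import model, simulate
from canmicro.bifurcation import EIG_TOL, branch_sweep, fold_location
from canmicro.model import ArchitectureParams


def random_params(rng):
    b1 = float(rng.integers(0, 2))
    b2 = 1.0 if b1 == 1.0 else float(rng.integers(0, 2))
    return ModelParams(arch=ArchitectureParams(b1=b1, b2=b2)).replace(
        He=float(rng.uniform(1.5, 7.0)), Hi=float(rng.uniform(3.0, 40.0)))


class TestFindEquilibria:
    def test_default_three_equilibria(self, table1):
        eqs = find_equilibria(0.0, table1)
        assert len(eqs) == 3
        low = eqs[0]
        assert low.stable
        assert -2.3 < low.v_py < -1.7
        assert not eqs[1].stable

    def test_high_drive_single_upper_equilibrium(self, table1):
        eqs = find_equilibria(200.0, table1)
        assert len(eqs) == 1
        assert eqs[0].v_py > 4.0

    def test_zero_gains_origin(self, zero_gain_params):
        eqs = find_equilibria(0.0, zero_gain_params)
        assert len(eqs) == 1
        assert np.abs(eqs[0].V).max() < 1e-9

    def test_matches_brute_force_scan(self, rng):
        # dual-route check: Newton multistart vs dense scalar-relation scan
        for _ in range(12):
            p = random_params(rng)
            p_ext = float(rng.uniform(-20.0, 150.0))
            newton = find_equilibria(p_ext, p)
            scan = equilibria_scan(p_ext, p)
            assert len(newton) == len(scan)
            for a, b in zip(newton, scan):
                assert a.v_py == pytest.approx(b.v_py, abs=1e-5)
                assert a.stable == b.stable

    def test_residual_small(self, table1):
        for eq in find_equilibria(35.0, table1):
            res = np.abs(model.rhs(model.embed(eq.V), 35.0, table1)).max()
            assert res < 1e-6


class TestBranch:
    def test_fold_locations_and_types(self, default_branch):
        folds = default_branch.folds()
        kinds = sorted(e.kind for e in folds)
        assert kinds == ["fold_sn", "fold_ss"]
        sn = next(e for e in folds if e.kind == "fold_sn")
        ss = next(e for e in folds if e.kind == "fold_ss")
        assert sn.p_ext == pytest.approx(78.25, abs=0.5)
        assert ss.p_ext == pytest.approx(-29.91, abs=0.5)

    def test_single_subcritical_hopf(self, default_branch):
        hopfs = default_branch.hopfs()
        assert len(hopfs) == 1
        assert hopfs[0].kind == "hopf_sub"
        # internal pin: the oscillatory pair crosses the axis here; the
        # independent scalar-reduction route must agree
        assert hopfs[0].p_ext == pytest.approx(-5.307, abs=0.05)
        assert hopfs[0].v_py == pytest.approx(6.0376, abs=0.005)

    def test_stability_flags_match_eigenvalues(self, default_branch):
        assert np.array_equal(
            default_branch.stable,
            default_branch.eigenvalues.real.max(axis=1) < EIG_TOL)

    def test_branch_matches_scalar_reduction(self, default_branch, table1):
        # every continuation point must lie on the exact reduced curve
        for k in range(0, len(default_branch.p_ext), 7):
            px, V, ok = branch_sweep(table1, np.array([default_branch.v_py[k]]))
            assert ok[0]
            assert px[0] == pytest.approx(default_branch.p_ext[k], abs=1e-5)

    def test_fold_has_zero_eigenvalue(self, table1):
        xf, pf = fold_location(table1, "lower")
        _, V, _ = branch_sweep(table1, np.array([xf]))
        ev = np.linalg.eigvals(model.jacobian(V[0], pf, table1))
        assert np.abs(ev.real).min() < 1e-2

    def test_simulation_returns_to_stable_equilibrium(self, table1):
        eqs = find_equilibria(0.0, table1)
        low = eqs[0]
        y0 = model.embed(low.V)
        y0[1] += 0.01
        vpy, _ = simulate.heun_core(
            y0[None, :], 3000, 1e-3,
            lambda k: (np.zeros(1), np.zeros(1)),
            simulate.make_rhs(table1), record="vpy")
        assert abs(vpy[-1, 0] - low.v_py) < 1e-4

    def test_simulation_departs_unstable_equilibrium(self, table1):
        mid = find_equilibria(0.0, table1)[1]
        assert not mid.stable
        y0 = model.embed(mid.V)
        y0[1] += 0.01
        vpy, _ = simulate.heun_core(
            y0[None, :], 5000, 1e-3,
            lambda k: (np.zeros(1), np.zeros(1)),
            simulate.make_rhs(table1), record="vpy")
        assert abs(vpy[-1, 0] - mid.v_py) > 1.0


class TestBistability:
    def test_default_bistable(self, table1):
        assert bistability_check(table1, 0.0) == "bistable_nodes"

    def test_two_population_monostable(self, two_pop):
        assert bistability_check(two_pop, 0.0) == "monostable"

    def test_zero_gains_monostable(self, zero_gain_params):
        assert bistability_check(zero_gain_params, 0.0) == "monostable"

    def test_memory_cells_are_bistable(self, table1):
        # cross-module consistency: a parameterization whose fingerprint
        # contains MEMORY must have >= 2 attractors at zero drive
        from canmicro import Behavior, fingerprint
        for he, hi in [(3.25, 22.0), (2.8, 16.0), (4.0, 30.0)]:
            p = table1.replace(He=he, Hi=hi)
            bm = fingerprint(p, intensities=np.linspace(80, 240, 5),
                             durations=[1.0, 1.5])
            if Behavior.MEMORY in bm.behavior_set():
                assert bistability_check(p, 0.0) != "monostable"


class TestCodim2:
    def test_default_inside_bistable_wedge(self, table1):
        # at Hi = 22 the two fold loci straddle the default He = 3.25:
        # zero drive lies between the folds, the precondition for memory
        upper = trace_codim2("fold_upper", [22.0], table1)
        lower = trace_codim2("fold_lower", [22.0], table1)
        assert upper.He[0] < 3.25 < lower.He[0]

    def test_two_population_split_flagged(self, two_pop):
        locus = trace_codim2("fold_upper", np.arange(3.5, 5.6, 0.5), two_pop)
        assert locus.kinds[0] == "fold_sn"
        assert locus.kinds[-1] == "fold_ss"
        assert len(locus.degenerate) == 1
        d = locus.degenerate[0]
        assert d["from"] == "fold_sn" and d["to"] == "fold_ss"

    def test_invalid_branch_type(self, table1):
        with pytest.raises(ValueError):
            trace_codim2("cusp", [22.0], table1)


class TestNiiSweep:
    def test_requires_disinhibited_architecture(self, table1):
        with pytest.raises(ValueError, match="b1 = 0, b2 = 0"):
            nii_sweep([0.0], table1)

    def test_zero_nii_reproduces_two_population(self, disinhibited, two_pop):
        (_, br0), = nii_sweep([0.0], disinhibited, p_ext_range=(-150.0, 250.0))
        br2 = continue_branch((-150.0, 250.0), two_pop, classify_hopf=False)
        ev0 = [(e.kind, round(e.p_ext, 3)) for e in br0.events]
        ev2 = [(e.kind, round(e.p_ext, 3)) for e in br2.events]
        assert ev0 == ev2

    def test_default_nii_fold_pair_preserves_upper_stability(self, disinhibited):
        (_, br), = nii_sweep([33.25], disinhibited)
        folds = br.folds()
        assert len(folds) == 2
        upper = max(folds, key=lambda e: e.v_py)
        assert upper.kind == "fold_sn"

    def test_events_vary_continuously(self, disinhibited):
        sweep = nii_sweep([28.0, 30.0, 32.0], disinhibited)
        lower_p = [min(br.folds(), key=lambda e: e.v_py).p_ext
                   for _, br in sweep]
        assert np.all(np.abs(np.diff(lower_p)) < 5.0)
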