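"""Tests of response classification, fingerprints and derived maps."""

import numpy as np
import pytest

from canmicro import (
    Behavior,
    ModelParams,
    WindowSpec,
    classify_response,
    deactivation_map,
    dynamic_function_map,
    fingerprint,
    run_protocol,
    stimulus_offset_phase_scan,
)
from canmicro.classify import _label_from_bits
from canmicro.simulate import Trajectory


def synthetic_trajectory(levels, table1, total=5.0, dt=1e-2):
    """Trajectory whose V_Py is piecewise constant at the window levels
    (pre, imm, asym); elsewhere at the lowest level."""
    t = np.arange(int(total / dt) + 1) * dt
    v = np.full(t.size, min(levels))
    for (a, b), lv in zip(((0.5, 1.0), (1.1, 3.5), (4.0, 5.0)), levels):
        v[(t >= a) & (t <= b)] = lv
    y = np.zeros((t.size, 10))
    y[:, 1] = v
    return Trajectory(t=t, y=y, p_ext=np.zeros(t.size), p_iin=np.zeros(t.size),
                      params=table1, dt=dt)


class TestLabelMapping:
    @pytest.mark.parametrize("bits,expected", [
        ((0, 1, 1), Behavior.MEMORY),
        ((1, 1, 1), Behavior.NONRESPONSIVE),   # uniformly above threshold
        ((0, 1, 0), Behavior.TRANSFER),
        ((0, 0, 0), Behavior.NONRESPONSIVE),
        ((0, 0, 1), Behavior.MEMORY),
    ])
    def test_triples(self, bits, expected):
        label, warning = _label_from_bits(*bits)
        assert label is expected
        assert warning is None

    @pytest.mark.parametrize("bits", [(1, 1, 0), (1, 0, 0), (1, 0, 1)])
    def test_exotic_triples_warn(self, bits):
        label, warning = _label_from_bits(*bits)
        assert label is Behavior.NONRESPONSIVE
        assert warning is not None

    def test_classify_from_trajectory(self, table1):
        traj = synthetic_trajectory((0.0, 5.0, 5.0), table1)
        lab = classify_response(traj)
        assert lab.behavior is Behavior.MEMORY
        assert lab.bits == (0, 1, 1)
        traj = synthetic_trajectory((0.0, 5.0, 0.0), table1)
        assert classify_response(traj).behavior is Behavior.TRANSFER

    def test_oscillation_flag(self, table1):
        traj = synthetic_trajectory((0.0, 5.0, 5.0), table1)
        traj.y[:, 1] += 0.4 * np.sin(40 * traj.t)  # ptp 0.8 > 0.5 mV
        assert classify_response(traj).oscillatory

    def test_short_trajectory_rejected(self, table1):
        traj = synthetic_trajectory((0, 0, 0), table1, total=3.0)
        with pytest.raises(ValueError, match="asymptotic"):
            classify_response(traj)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(prestimulus=(1.0, 0.5))
        with pytest.raises(ValueError, match="disjoint"):
            WindowSpec(prestimulus=(0.5, 1.2), immediate=(1.1, 3.5))


class TestFingerprint:
    def test_zero_intensity_grid_nonresponsive(self, table1):
        bm = fingerprint(table1, intensities=[0.0, 0.0], durations=[0.5, 1.0])
        assert all(b is Behavior.NONRESPONSIVE for b in bm.labels.ravel())

    def test_empty_grid_rejected(self, table1):
        with pytest.raises(ValueError):
            fingerprint(table1, intensities=[], durations=[0.5])

    def test_matches_single_runs(self, table1):
        # the batched grid gives the same labels as one-at-a-time runs
        ints, durs = [60.0, 100.0], [0.6, 1.4]
        bm = fingerprint(table1, ints, durs)
        for i, inten in enumerate(ints):
            for j, dur in enumerate(durs):
                single = classify_response(run_protocol(inten, dur, table1))
                assert bm.labels[i, j] is single.behavior
                assert tuple(bm.bits[i, j]) == single.bits

    def test_determinism(self, table1):
        a = fingerprint(table1, [80, 120], [0.6, 1.1])
        b = fingerprint(table1, [80, 120], [0.6, 1.1])
        assert np.array_equal(a.labels, b.labels)

    def test_supersampling_invariance(self, table1):
        # halving dt leaves the labels unchanged on a small grid
        ints, durs = [70.0, 110.0, 180.0], [0.55, 1.05, 1.5]
        a = fingerprint(table1, ints, durs, dt=1e-3)
        b = fingerprint(table1, ints, durs, dt=5e-4)
        assert np.array_equal(a.labels, b.labels)

    def test_long_format_export(self, tmp_path, table1):
        bm = fingerprint(table1, [80, 120], [0.6, 1.1])
        path = tmp_path / "fp.csv"
        bm.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert set(df.columns) == {"intensity", "duration", "label", "bits", "osc_flag"}
        assert len(df) == 4


class TestDynamicFunctionMap:
    def test_default_cell_contains_all_behaviors(self, table1):
        m = dynamic_function_map([3.25], [22.0], table1)
        assert m.behavior_sets[0, 0] == frozenset(Behavior)

    def test_strong_inhibition_nonresponsive(self, table1):
        # far above the bistable wedge the circuit ignores the stimulus
        m = dynamic_function_map([3.25], [120.0], table1,
                                 intensities=np.linspace(50, 250, 5),
                                 durations=np.linspace(0.5, 1.5, 5))
        assert m.behavior_sets[0, 0] == {Behavior.NONRESPONSIVE}
        assert m.modal[0, 0] is Behavior.NONRESPONSIVE

    def test_csv_export(self, tmp_path, table1):
        m = dynamic_function_map([3.25], [22.0], table1,
                                 intensities=[100.0], durations=[0.5, 1.5])
        m.to_csv(tmp_path / "dfmap.csv")
        assert (tmp_path / "dfmap.csv").exists()


class TestDeactivation:
    def test_requires_bistability(self, two_pop):
        with pytest.raises(ValueError, match="monostable"):
            deactivation_map(two_pop, [0, 50], [0.05])

    def test_zero_impulse_stays_active(self, table1):
        dm = deactivation_map(table1, iin_intensities=[0.0, 60.0],
                              iin_durations=[0.05, 0.15])
        assert not dm.deactivated[0].any()      # no perturbation, no reset
        assert dm.deactivated[1].all()          # a weak brief impulse resets

    def test_duration_monotonicity_on_grid(self, table1):
        dm = deactivation_map(table1, iin_intensities=np.linspace(0, 80, 5),
                              iin_durations=np.linspace(0.02, 0.2, 5))
        d = dm.deactivated
        # on the tested grid, longer impulses never undo a deactivation
        assert np.all(d[:, 1:] >= d[:, :-1])


class TestPhaseScan:
    def test_alternation_near_boundary(self, table1):
        labels = [l.behavior for l in stimulus_offset_phase_scan(table1)]
        assert Behavior.TRANSFER in labels
        assert Behavior.MEMORY in labels

    def test_long_duration_memory(self, table1):
        labels = stimulus_offset_phase_scan(table1, durations=[1.5, 1.6])
        assert all(l.behavior is Behavior.MEMORY for l in labels)

    def test_subthreshold_uniform_nonresponsive(self, table1):
        labels = stimulus_offset_phase_scan(table1, intensity=70.0)
        assert all(l.behavior is Behavior.NONRESPONSIVE for l in labels)
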