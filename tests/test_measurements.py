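"""Unit tests for APD/rise-time/CV/Q10 readouts and the tip detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioheat.fields_pde import Grid2D
from cardioheat.measurements import (
    NoActivation,
    NoRepolarization,
    Trace,
    apd,
    conduction_velocity,
    heat_accumulation,
    q10,
    rise_time,
    termination_time,
    tip_locations,
)


def make_trace(t, Vm, x=6.0, y=5.0):
    return Trace(x=x, y=y, t=np.asarray(t, float), Vm=np.asarray(Vm, float))


def square_pulse(t0=10.0, t1=110.0, dt=0.5, total=200.0, lo=-85.0, hi=30.0):
    t = np.arange(0.0, total + dt / 2, dt)
    Vm = np.where((t >= t0) & (t < t1), hi, lo)
    return make_trace(t, Vm)


class TestAPD:
    def test_square_pulse_duration(self):
        # -85 -> 30 jump between samples: crossings interpolate to the jump
        tr = square_pulse()
        assert apd(tr) == pytest.approx(100.0, abs=0.5)

    def test_triangular_pulse_interpolated(self):
        # -85 -> 35 -> -85 over [0, 100]; threshold -80 crossed at
        # t = 50/120*5 = 25/12 and t = 100 - 25/12 -> APD = 95.8333
        t = np.linspace(0.0, 100.0, 201)
        Vm = 35.0 - 120.0 * np.abs(t - 50.0) / 50.0
        assert apd(make_trace(t, Vm)) == pytest.approx(95.833333, abs=1e-3)

    def test_no_activation_raises(self):
        t = np.linspace(0, 100, 101)
        with pytest.raises(NoActivation):
            apd(make_trace(t, np.full_like(t, -85.0)))

    def test_no_repolarization_raises(self):
        t = np.linspace(0, 100, 101)
        Vm = np.where(t > 50, 30.0, -85.0)
        with pytest.raises(NoRepolarization):
            apd(make_trace(t, Vm))

    def test_shift_invariance(self):
        tr = square_pulse()
        shifted = make_trace(tr.t, tr.Vm)
        shifted.t = tr.t + 123.0
        assert apd(shifted) == pytest.approx(apd(tr))

    def test_episode_selection(self):
        t = np.arange(0.0, 400.0, 0.5)
        Vm = np.full_like(t, -85.0)
        Vm[(t >= 10) & (t < 60)] = 30.0
        Vm[(t >= 200) & (t < 350)] = 30.0
        assert apd(make_trace(t, Vm), episode=0) == pytest.approx(50.0, abs=0.5)
        assert apd(make_trace(t, Vm), episode=1) == pytest.approx(150.0, abs=0.5)


class TestRiseTime:
    def test_linear_ramp(self):
        # -85 -> 40 over 2.5 ms: crossing -80 to 30 takes 110/125*2.5 = 2.2 ms
        t = np.linspace(0.0, 2.5, 26)
        Vm = -85.0 + (125.0 / 2.5) * t
        assert rise_time(make_trace(t, Vm)) == pytest.approx(2.2, abs=1e-9)

    def test_instant_jump_bounded_by_dt(self):
        tr = square_pulse(dt=0.25)
        assert rise_time(tr) <= 0.25

    def test_missing_level_raises(self):
        t = np.linspace(0, 10, 11)
        Vm = np.where(t > 5, -50.0, -85.0)  # never reaches +30
        with pytest.raises(NoActivation):
            rise_time(make_trace(t, Vm))


class TestConductionVelocity:
    def make_travelling_pair(self, c=0.05):
        # Vm(x - c t): probe separation 1 cm -> delay 1/c ms
        t = np.arange(0.0, 100.0, 0.1)
        def wave(x):
            return -85.0 + 125.0 / (1.0 + np.exp(-(c * t - x + 2.0) / 0.05))
        a = make_trace(t, wave(3.0), x=5.0, y=5.0)
        b = make_trace(t, wave(4.0), x=6.0, y=5.0)
        return a, b

    def test_constructed_speed(self):
        a, b = self.make_travelling_pair(c=0.05)
        assert conduction_velocity(a, b) == pytest.approx(0.5, rel=1e-3)

    def test_probe_swap_invariance(self):
        a, b = self.make_travelling_pair()
        assert conduction_velocity(b, a) == pytest.approx(
            conduction_velocity(a, b)
        )

    def test_identical_probes_rejected(self):
        a, _ = self.make_travelling_pair()
        with pytest.raises(ValueError):
            conduction_velocity(a, a)


class TestQ10:
    def test_table_values(self):
        assert q10(644.0, 266.0, 27.0, 37.0, "apd") == pytest.approx(2.42, abs=0.005)
        assert q10(0.337, 0.741, 27.0, 37.0, "cv") == pytest.approx(2.199, abs=0.005)

    def test_equal_values_give_unity(self):
        assert q10(1.0, 1.0, 27.0, 37.0, "apd") == 1.0
        assert q10(1.0, 1.0, 27.0, 37.0, "cv") == 1.0

    @given(
        x=st.floats(min_value=0.01, max_value=100.0),
        y=st.floats(min_value=0.01, max_value=100.0),
        s=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, x, y, s):
        for kind in ("apd", "cv"):
            assert q10(x * s, y * s, 27.0, 37.0, kind) == pytest.approx(
                q10(x, y, 27.0, 37.0, kind), rel=1e-9
            )

    def test_validation(self):
        with pytest.raises(ValueError):
            q10(-1.0, 1.0, 27.0, 37.0, "apd")
        with pytest.raises(ValueError):
            q10(1.0, 1.0, 37.0, 27.0, "apd")
        with pytest.raises(ValueError):
            q10(1.0, 1.0, 27.0, 37.0, "resistance")


class TestTermination:
    def test_all_resting_terminates_at_zero(self):
        snaps = [np.full((4, 4), -85.0) for _ in range(5)]
        assert termination_time(range(0, 150, 30), snaps) == 0.0

    def test_persistent_activity_returns_none(self):
        snaps = [np.full((4, 4), 0.0) for _ in range(5)]
        assert termination_time(range(0, 150, 30), snaps) is None

    def test_earliest_quiescent_time(self):
        active = np.full((4, 4), 0.0)
        quiet = np.full((4, 4), -85.0)
        snaps = [active, active, quiet, quiet, quiet]
        assert termination_time([0, 30, 60, 90, 120], snaps) == 60.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            termination_time([], [])


class TestTipLocations:
    def test_planar_wave_has_no_tips(self):
        grid = Grid2D.from_extent(2.0, 2.0, 0.05)
        X, _ = grid.meshgrid()
        def wave(shift):
            return -85.0 + 125.0 / (1.0 + np.exp((X - 1.0 - shift) / 0.1))
        assert tip_locations(wave(0.05), wave(0.0), grid) == []

    def test_rotating_spiral_tip_near_center(self):
        # rigidly rotating Archimedean spiral phase field; the isopotential /
        # d(Vm)/dt=0 crossing must sit within 2 dx of the rotation center
        grid = Grid2D.from_extent(4.0, 4.0, 0.04)
        X, Y = grid.meshgrid()
        cx = cy = 2.0
        r = np.hypot(X - cx, Y - cy)
        th = np.arctan2(Y - cy, X - cx)
        def frame(phase):
            return -22.5 + 62.5 * np.cos(th - 2.0 * np.pi * r / 1.5 - phase)
        tips = tip_locations(frame(0.12), frame(0.0), grid)
        assert len(tips) >= 1
        d = min(np.hypot(tx - cx, ty - cy) for tx, ty in tips)
        assert d <= 2 * grid.dx

    def test_deterministic(self):
        grid = Grid2D.from_extent(4.0, 4.0, 0.08)
        X, Y = grid.meshgrid()
        th = np.arctan2(Y - 2, X - 2)
        r = np.hypot(X - 2, Y - 2)
        a = -22.5 + 62.5 * np.cos(th - 4 * r)
        b = -22.5 + 62.5 * np.cos(th - 4 * r - 0.2)
        assert tip_locations(a, b, grid) == tip_locations(a.copy(), b.copy(), grid)


class TestHeatAccumulation:
    def test_zero_at_equilibrium(self):
        grid = Grid2D.from_extent(1.0, 1.0, 0.1)
        T = np.full(grid.shape, 37.0)
        dT, mx, _ = heat_accumulation(T, np.full(grid.shape, 37.0), grid)
        assert mx == 0.0 and np.all(dT == 0.0)

    def test_argmax_location(self):
        grid = Grid2D.from_extent(1.0, 1.0, 0.1)
        T = np.full(grid.shape, 30.0)
        T[3, 7] = 30.5
        dT, mx, (x, y) = heat_accumulation(T, 30.0, grid)
        assert mx == pytest.approx(0.5)
        assert (x, y) == pytest.approx((0.7, 0.3))


class TestTraceValidation:
    def test_nonuniform_axis_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0.0, 1.0, 3.0], [0.0, 0.0, 0.0])

    def test_decreasing_axis_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0.0, -1.0, -2.0], [0.0, 0.0, 0.0])
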