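"""Integrator tests: BDF2 formula and order, fixed points, mode contracts,
isothermal equivalence, heat relaxation, and bidomain/monodomain agreement."""

import numpy as np
import pytest

from cardioheat.fields_pde import (
    FieldState,
    Grid2D,
    Tensor2,
    ThermalParams,
    TissueParams,
)
from cardioheat.ionic_models import IonicModelSpec
from cardioheat.measurements import Trace, activation_time, conduction_velocity
from cardioheat.time_stepping import (
    CoupledSimulator,
    SolverConfig,
    StepHistory,
    StimulusEvent,
    bdf2_derivative,
    simulate,
)


def uniform_state(grid, Vm, W, T=37.0):
    return FieldState(
        Vm=np.full(grid.shape, float(Vm)),
        phi_e=np.zeros(grid.shape),
        W=np.full(grid.shape, float(W)),
        T=np.full(grid.shape, float(T)),
    )


class TestBDF2Derivative:
    def test_constant_sequence(self):
        assert bdf2_derivative(3.0, 3.0, 3.0, 0.5) == 0.0

    def test_exact_on_linear(self):
        assert bdf2_derivative(2.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_exact_on_quadratic(self):
        # y = t^2 at t = 2, 1, 0 -> derivative 4 at t = 2
        assert bdf2_derivative(4.0, 1.0, 0.0, 1.0) == pytest.approx(4.0)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            bdf2_derivative(1.0, 1.0, 1.0, 0.0)


class TestFixedPointsAndModes:
    def test_ms_resting_equilibrium_is_discrete_fixed_point(self):
        grid = Grid2D(nx=9, ny=5, dx=0.1, dy=0.1)
        sim = CoupledSimulator(grid, IonicModelSpec(kind="ms"), config=SolverConfig(dt=0.3))
        st = uniform_state(grid, -85.0, 1.0)
        hist = StepHistory(prev=st.copy(), curr=st, time=0.0)
        new = sim.step_coupled(hist, 37.0, 37.0, first_step=True)
        assert np.max(np.abs(new.Vm + 85.0)) < 1e-10
        assert np.max(np.abs(new.W - 1.0)) < 1e-10
        assert np.max(np.abs(new.T - 37.0)) < 1e-10

    def test_ionic_only_mode_pins_temperature_to_tstar(self):
        grid = Grid2D(nx=9, ny=5, dx=0.1, dy=0.1)
        cfg = SolverConfig(dt=0.3, coupling_mode="ionic_only_static_T")
        sim = CoupledSimulator(grid, IonicModelSpec(kind="ms"), config=cfg)
        st = uniform_state(grid, 0.0, 0.9, T=30.0)
        hist = StepHistory(prev=st.copy(), curr=st, time=0.0)
        new = sim.step_coupled(hist, 30.0, 30.0, first_step=True)
        assert np.array_equal(new.T, np.full(grid.shape, 30.0))

    def test_coupled_step_at_uniform_37_bitmatches_isothermal_bidomain(self):
        # thermal factors are exactly 1 at Ta=37, so one step of the coupled
        # solver from T=37 equals one step of the temperature-stripped
        # bidomain (= ionic_only mode with T*=37) bit for bit
        grid = Grid2D(nx=33, ny=5, dx=0.05, dy=0.05)
        X, _ = grid.meshgrid()
        st = uniform_state(grid, -85.0, 0.9)
        st.Vm = np.where(X < 0.4, 40.0, -85.0).astype(float)
        out = {}
        for mode in ("heat_bidomain", "ionic_only_static_T"):
            cfg = SolverConfig(dt=0.2, coupling_mode=mode)
            sim = CoupledSimulator(grid, IonicModelSpec(kind="ms"), config=cfg)
            hist = StepHistory(prev=st.copy(), curr=st.copy(), time=0.0)
            out[mode] = sim.step_coupled(hist, 37.0, 37.0, first_step=True)
        assert np.array_equal(out["heat_bidomain"].Vm, out["ionic_only_static_T"].Vm)
        assert np.array_equal(out["heat_bidomain"].W, out["ionic_only_static_T"].W)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(coupling_mode="heat_tridomain")


class TestHeatBlock:
    def test_source_free_relaxation_matches_closed_form(self):
        # uniform T0 != T*, resting electrics: T(t) = T* + (T0-T*) exp(-bc t/(rho cp))
        grid = Grid2D(nx=3, ny=3, dx=0.1, dy=0.1)
        tp = ThermalParams()
        res = simulate(
            grid, IonicModelSpec(kind="ms"),
            uniform_state(grid, -85.0, 1.0, T=30.0),
            duration=2000.0, config=SolverConfig(dt=0.3),
            tstar_fn=lambda t: 37.0, probes=((0.1, 0.1),),
        )
        T = res.traces["T"][0]
        exact = 37.0 + (30.0 - 37.0) * np.exp(-tp.bc / tp.rho_cp * res.times)
        assert np.max(np.abs(T - exact)) / 7.0 < 1e-6

    def test_heat_positivity_with_nonnegative_source(self):
        # planar wave on a coarse strip: T never drops below T* - 1e-9
        grid = Grid2D.from_extent(4.0, 0.2, 0.05)
        X, _ = grid.meshgrid()
        st = uniform_state(grid, -85.0, 0.9)
        st.Vm = np.where(X < 0.5, 40.0, -85.0).astype(float)
        res = simulate(
            grid, IonicModelSpec(kind="ms"), st, duration=60.0,
            config=SolverConfig(dt=0.2), probes=((2.0, 0.1),),
            snapshot_stride=10.0,
        )
        tmin = min(np.min(s.T) for s in res.snapshots)
        assert tmin >= 37.0 - 1e-9


class TestBidomainMonodomainEquivalence:
    def test_planar_cv_agreement_under_proportional_tensors(self):
        # Gi = lam*Ge (proportional): the monodomain reduction with
        # G = Gi/(1+lam) is exact, so planar CV agrees within 2%
        lam = 1.5
        Gi = Tensor2(3.0, 0.315)
        tissue = TissueParams(Gi=Gi, Ge=Gi.scaled(1.0 / lam))
        grid = Grid2D.from_extent(4.0, 0.2, 0.05)
        X, _ = grid.meshgrid()
        st = uniform_state(grid, -85.0, 0.9)
        st.Vm = np.where(X < 0.5, 40.0, -85.0).astype(float)
        cvs = {}
        for mode in ("heat_bidomain", "heat_monodomain"):
            cfg = SolverConfig(dt=0.2, coupling_mode=mode, lam=lam)
            res = simulate(
                grid, IonicModelSpec(kind="ms"), st.copy(), duration=60.0,
                config=cfg, tissue=tissue, probes=((2.0, 0.1), (3.0, 0.1)),
            )
            tr = [
                Trace(x=p[0], y=p[1], t=res.times, Vm=res.trace(i))
                for i, p in enumerate(res.probes)
            ]
            cvs[mode] = conduction_velocity(tr[0], tr[1])
        assert cvs["heat_bidomain"] == pytest.approx(
            cvs["heat_monodomain"], rel=0.02
        )


class TestRunSimulation:
    def make_strip_run(self, duration=40.0, tstar=37.0, dt=0.2):
        grid = Grid2D.from_extent(4.0, 0.2, 0.05)
        X, _ = grid.meshgrid()
        st = uniform_state(grid, -85.0, 0.9, T=tstar)
        st.Vm = np.where(X < 0.5, 40.0, -85.0).astype(float)
        return simulate(
            grid, IonicModelSpec(kind="ms"), st, duration=duration,
            config=SolverConfig(dt=dt), tstar_fn=lambda t: tstar,
            probes=((1.5, 0.1), (2.5, 0.1)),
        )

    def test_trace_length_bookkeeping(self):
        res = self.make_strip_run(duration=40.0, dt=0.3)
        assert len(res.times) == int(np.floor(40.0 / 0.3)) + 1
        assert res.traces["Vm"].shape == (2, len(res.times))

    def test_outward_propagation_ordering(self):
        res = self.make_strip_run()
        t1 = activation_time(Trace(1.5, 0.1, res.times, res.trace(0)))
        t2 = activation_time(Trace(2.5, 0.1, res.times, res.trace(1)))
        assert t1 < t2

    def test_warm_tissue_activates_earlier(self):
        t_act = {}
        for tstar in (31.0, 43.0):
            res = self.make_strip_run(duration=90.0, tstar=tstar, dt=0.1)
            t_act[tstar] = activation_time(
                Trace(2.5, 0.1, res.times, res.trace(1))
            )
        assert t_act[43.0] < t_act[31.0]

    def test_determinism_bitwise(self):
        a = self.make_strip_run()
        b = self.make_strip_run()
        assert np.array_equal(a.traces["Vm"], b.traces["Vm"])
        assert np.array_equal(a.traces["T"], b.traces["T"])

    def test_stimulus_event_applied(self):
        grid = Grid2D.from_extent(2.0, 0.2, 0.05)
        X, _ = grid.meshgrid()
        st = uniform_state(grid, -85.0, 1.0)
        ev = StimulusEvent(time=5.0, mask=(X < 0.3), Vm_value=40.0)
        res = simulate(
            grid, IonicModelSpec(kind="ms"), st, duration=10.0,
            config=SolverConfig(dt=0.5), probes=((0.0, 0.1),), stimuli=[ev],
        )
        k = np.searchsorted(res.times, 5.0)
        assert np.all(res.trace(0)[: k] == -85.0)
        assert res.trace(0)[k + 1] > -80.0
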