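"""Declarative experiment builders.

Four named experiments are provided:

* ``planar_q10`` — a planar wave launched from a small excited disc at the
  center of the sheet, used to read out APD, rise time and conduction
  velocity at a prescribed perfusion temperature T* (the Q10 study).
* ``single_spiral`` — one Aliev--Panfilov spiral (a = 0.1) initiated by
  cross-field S1--S2 stimulation, optionally with global hypothermia or
  regional disc cooling.
* ``multi_spiral`` — three spirals (a = 0.1, mu1 = 0.135, eps0 = 0.001) with
  cooling switched on at t = 600 ms.
* ``domain_size_check`` — the multi-spiral study on a 13 cm x 13 cm sheet.

The perfusion setpoint T* doubles as the arterial-blood temperature and the
cooling setpoint; the initial tissue temperature always equals the t = 0 T*
field, so a cooling schedule starting at t = 0 is an instantaneously cooled
tissue while t_on > 0 leaves the tissue at body temperature first.

All builders are deterministic; rerunning one reproduces its state bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .fields_pde import FieldState, Grid2D, ThermalParams, TissueParams
from .ionic_models import APParams, IonicModelSpec, VoltageScale
from .measurements import tip_locations
from .time_stepping import (
    CoupledSimulator,
    SimulationResult,
    SolverConfig,
    StepHistory,
    simulate,
)

__all__ = [
    "CoolingSpec",
    "Protocol",
    "ProtocolError",
    "S1S2Params",
    "planar_initial_state",
    "tstar_field",
    "s1s2_spiral_state",
    "multi_spiral_state",
    "build_protocol",
    "run_protocol",
]

PROTOCOL_NAMES = ("planar_q10", "single_spiral", "multi_spiral", "domain_size_check")


class ProtocolError(RuntimeError):
    """A protocol builder failed its own contract (e.g. wrong tip count)."""

    def __init__(self, message: str, diagnostic_state: FieldState | None = None):
        super().__init__(message)
        self.diagnostic_state = diagnostic_state


@dataclass(frozen=True)
class CoolingSpec:
    """Perfusion-setpoint schedule: where and when T* deviates from body.

    region "global" sets the whole domain to T_cool after t_on; region
    "disc" cools a disc of the given radius centered at ``center`` while the
    rest of the tissue stays at T_body.
    """

    region: str = "global"  # "global" | "disc"
    T_cool: float = 30.0
    T_body: float = 37.0
    t_on: float = 0.0
    center: tuple[float, float] = (5.0, 5.0)
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.region not in ("global", "disc"):
            raise ValueError(f"unknown cooling region {self.region!r}")
        if self.region == "disc" and self.radius <= 0:
            raise ValueError("disc radius must be positive")


def tstar_field(grid: Grid2D, cooling: CoolingSpec | None, t: float):
    """The perfusion temperature field T*(x, t) in degC.

    Piecewise constant with a node-resolved boundary; uniform T_body before
    t_on (and whenever no cooling is specified).
    """
    T_body = 37.0 if cooling is None else cooling.T_body
    if cooling is None or t < cooling.t_on:
        return np.full(grid.shape, T_body)
    if cooling.region == "global":
        return np.full(grid.shape, cooling.T_cool)
    cx, cy = cooling.center
    r = cooling.radius
    if cx - r < 0 or cx + r > grid.Lx or cy - r < 0 or cy + r > grid.Ly:
        raise ValueError("cooling disc extends outside the domain")
    X, Y = grid.meshgrid()
    out = np.full(grid.shape, T_body)
    out[(X - cx) ** 2 + (Y - cy) ** 2 <= r**2] = cooling.T_cool
    return out


def planar_initial_state(
    grid: Grid2D,
    scale: VoltageScale | None = None,
    Tstar0: np.ndarray | float = 37.0,
    W0: float = 0.9,
) -> FieldState:
    """Excited disc of radius sqrt(0.5) cm at the domain center.

    Vm = v_peak inside (x-cx)^2 + (y-cy)^2 < 0.5, v_rest elsewhere;
    phi_e = 0, W = 0.9, T = the t = 0 perfusion field.
    """
    scale = scale or VoltageScale()
    X, Y = grid.meshgrid()
    cx, cy = grid.Lx / 2.0, grid.Ly / 2.0
    Vm = np.where(
        (X - cx) ** 2 + (Y - cy) ** 2 < 0.5, scale.v_peak, scale.v_rest
    ).astype(float)
    T = np.broadcast_to(np.asarray(Tstar0, dtype=float), grid.shape).copy()
    return FieldState(
        Vm=Vm,
        phi_e=np.zeros(grid.shape),
        W=np.full(grid.shape, W0),
        T=T,
    )


# ---------------------------------------------------------------------------
# S1-S2 spiral initiation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class S1S2Params:
    """Cross-field stimulation constants (calibrated once for the AP model).

    S1 is a conditioning stripe on the x = 0 edge; the repolarization tail is
    monitored at the domain center and, ``s2_delay`` ms after the center has
    recovered below ``recovery_level``, the premature S2 stimulus excites a
    region whose free end curls into the spiral; the state is then allowed to
    settle before being returned.
    """

    s1_width: float = 0.5  # cm
    recovery_level: float = -72.5  # mV
    s2_delay: float = 0.0  # ms
    settle: float = 150.0  # ms
    max_wait: float = 1500.0  # ms safety cap on the monitoring phase


def _run_initiation(
    grid: Grid2D,
    model_spec: IonicModelSpec,
    config: SolverConfig,
    tissue: TissueParams,
    thermal: ThermalParams,
    s2_masks: Callable[[Grid2D], list[np.ndarray]],
    p: S1S2Params,
    expected_tips: int,
) -> FieldState:
    model = model_spec.build()
    scale = model.scale
    X, Y = grid.meshgrid()

    Vm = np.where(X < p.s1_width, scale.v_peak, scale.v_rest).astype(float)
    state = FieldState(
        Vm=Vm,
        phi_e=np.zeros(grid.shape),
        W=np.full(grid.shape, model.rest_W, dtype=float),
        T=np.full(grid.shape, 37.0),
    )
    sim = CoupledSimulator(grid, model_spec, tissue, thermal, config)
    hist = StepHistory(prev=state.copy(), curr=state, time=0.0)
    jc, ic = grid.node_index(grid.Lx / 2.0, grid.Ly / 2.0)

    dt = config.dt
    t = 0.0
    excited = False
    t_s2 = None
    s2_applied = False
    t_end = None
    prev_for_tips = None
    first = True
    while True:
        if t_s2 is not None and not s2_applied and t >= t_s2 - 1e-9:
            hist.curr.Vm = hist.curr.Vm.copy()
            for mask in s2_masks(grid):
                hist.curr.Vm[mask] = scale.v_peak
            hist.prev = hist.curr.copy()  # restart multistep history at the jump
            s2_applied = True
            t_end = t + p.settle
        new = sim.step_coupled(hist, Tstar_np1=37.0, Tstar_n=37.0, first_step=first)
        first = False
        hist = StepHistory(prev=hist.curr, curr=new, time=t + dt)
        t += dt
        center_v = new.Vm[jc, ic]
        if not excited and center_v > -30.0:
            excited = True
        if excited and t_s2 is None and center_v < p.recovery_level:
            t_s2 = t + p.s2_delay
        if t_end is not None and t >= t_end - 1e-9:
            prev_for_tips = hist.prev.Vm
            break
        if t_s2 is None and t > p.max_wait:
            raise ProtocolError(
                "S1 wave never recovered at the domain center "
                f"within {p.max_wait} ms", new
            )

    tips = tip_locations(hist.curr.Vm, prev_for_tips, grid)
    if len(tips) != expected_tips:
        raise ProtocolError(
            f"spiral initiation produced {len(tips)} phase singularities "
            f"(expected {expected_tips}); tips = {tips}",
            hist.curr,
        )
    return hist.curr


def s1s2_spiral_state(
    grid: Grid2D,
    model_spec: IonicModelSpec,
    config: SolverConfig,
    tissue: TissueParams | None = None,
    thermal: ThermalParams | None = None,
    s1s2: S1S2Params | None = None,
) -> FieldState:
    """Initiate exactly one spiral by cross-field S1-S2 stimulation at 37 degC.

    S2 excites the quadrant x < Lx/2, y < Ly/2 once the S1 tail has cleared
    the domain center; the broken end of the S2 front curls into a single
    rotor.  Raises ProtocolError (with the offending state attached) if the
    detected singularity count differs from one.
    """
    p = s1s2 or S1S2Params()

    def masks(g: Grid2D):
        X, Y = g.meshgrid()
        return [(X < g.Lx / 2.0) & (Y < g.Ly / 2.0)]

    return _run_initiation(
        grid, model_spec, config, tissue or TissueParams(),
        thermal or ThermalParams(), masks, p, expected_tips=1,
    )


def multi_spiral_state(
    grid: Grid2D,
    model_spec: IonicModelSpec,
    config: SolverConfig,
    tissue: TissueParams | None = None,
    thermal: ThermalParams | None = None,
    s1s2: S1S2Params | None = None,
) -> FieldState:
    """Initiate exactly three spirals (staggered S2 patches), deterministic."""
    p = s1s2 or S1S2Params()

    def masks(g: Grid2D):
        X, Y = g.meshgrid()
        half = X < g.Lx / 2.0
        return [
            half & (Y < 0.25 * g.Ly),  # touches the bottom edge: one free end
            half & (Y > 0.45 * g.Ly) & (Y < 0.70 * g.Ly),  # interior: two ends
        ]

    return _run_initiation(
        grid, model_spec, config, tissue or TissueParams(),
        thermal or ThermalParams(), masks, p, expected_tips=3,
    )


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """A fully specified experiment; run it with :func:`run_protocol`."""

    name: str
    domain: tuple[float, float]  # (Lx, Ly) cm
    dx: float
    duration: float  # ms
    model: IonicModelSpec
    cooling: CoolingSpec | None
    probes: tuple[tuple[float, float], ...]
    dt: float
    snapshot_stride: float | None = 30.0
    tissue: TissueParams = field(default_factory=TissueParams)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    s1s2: S1S2Params = field(default_factory=S1S2Params)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        Lx, Ly = self.domain
        for (px, py) in self.probes:
            if not (0 <= px <= Lx and 0 <= py <= Ly):
                raise ValueError(f"probe ({px}, {py}) outside the domain")

    def grid(self) -> Grid2D:
        return Grid2D.from_extent(self.domain[0], self.domain[1], self.dx)

    def tstar_fn(self, grid: Grid2D):
        return lambda t: tstar_field(grid, self.cooling, t)

    def initial_state(self, grid: Grid2D, config: SolverConfig) -> FieldState:
        T0 = tstar_field(grid, self.cooling, 0.0)
        if self.name == "planar_q10":
            return planar_initial_state(grid, self.model.scale, T0)
        if self.name == "single_spiral":
            st = s1s2_spiral_state(
                grid, self.model, config, self.tissue, self.thermal, self.s1s2
            )
        else:
            st = multi_spiral_state(
                grid, self.model, config, self.tissue, self.thermal, self.s1s2
            )
        st = st.copy()
        st.T = np.asarray(T0, dtype=float).copy()  # initial T equals t=0 T* field
        return st


def build_protocol(name: str, **options) -> Protocol:
    """Instantiate one of the named experiments with its defaults.

    Common options: ``tstar`` (planar_q10 perfusion temperature), ``domain``,
    ``dx``, ``dt``, ``duration``, ``cooling`` (a CoolingSpec or None),
    ``probes``, ``snapshot_stride``, ``s1s2``, and ionic parameter
    ``overrides`` (dict applied to the active kinetics).
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")

    overrides = options.pop("overrides", {})
    if name == "planar_q10":
        tstar = float(options.pop("tstar", 37.0))
        domain = options.pop("domain", (10.0, 10.0))
        dx = options.pop("dx", 0.025)
        dt = options.pop("dt", 0.3)
        duration = options.pop("duration", 750.0)
        model = IonicModelSpec(kind="ms")
        if overrides:
            model = model.with_overrides(**overrides)
        Lx, Ly = domain
        y0 = Ly / 2.0
        # APD/rise probe at (Lx/2+1, Ly/2) = the reference point (6, 5); CV from
        # the first and last probes (1 cm apart).  Probes start outside the
        # initial excited disc (radius sqrt(0.5) ~ 0.71 cm) so activation
        # times are propagation times.
        probes = options.pop(
            "probes",
            ((Lx / 2 + 1.0, y0), (Lx / 2 + 1.5, y0), (Lx / 2 + 2.0, y0)),
        )
        cooling = options.pop(
            "cooling",
            CoolingSpec(region="global", T_cool=tstar, T_body=tstar, t_on=0.0),
        )
        proto = Protocol(
            name=name, domain=domain, dx=dx, duration=duration, model=model,
            cooling=cooling, probes=tuple(probes), dt=dt,
            snapshot_stride=options.pop("snapshot_stride", 30.0),
            s1s2=options.pop("s1s2", S1S2Params()),
        )
    else:
        # Spiral studies run desk-scaled by default: the AP depolarization
        # front is ~0.1 mm wide transversely, so resolving it (dx ~ 0.3 mm,
        # required for transverse propagation at all) on the full 10 cm
        # square is out of reach of a single workstation CPU.  The default
        # 4 cm square at dx = 0.03125 cm is the smallest sheet on which the
        # initiated activity is reliably sustained at normothermia for the
        # full study horizon.  Pass domain=/dx= for full-scale runs.
        domain = options.pop(
            "domain", (5.25, 5.25) if name == "domain_size_check" else (4.0, 4.0)
        )
        dx = options.pop("dx", 0.03125)
        dt = options.pop("dt", 0.45)
        if name == "single_spiral":
            ap = APParams(a=0.1)
            duration = options.pop("duration", 1680.0)
            default_cooling = None
        else:
            ap = APParams(a=0.1, mu1=0.135, eps0=0.001)
            duration = options.pop("duration", 1950.0)
            default_cooling = None
        if overrides:
            from dataclasses import replace as _rep

            ap = _rep(ap, **overrides)
        model = IonicModelSpec(kind="ap", ap=ap)
        cooling = options.pop("cooling", default_cooling)
        Lx, Ly = domain
        if cooling is not None and cooling.region == "disc":
            # keep the disc centered; the reference radius 2 cm belongs to
            # the full 10 cm sheet (= 0.2 L), so rescale it with the domain
            radius = cooling.radius
            if radius == 2.0 and (Lx, Ly) != (10.0, 10.0):
                radius = 0.2 * min(Lx, Ly)
            cooling = replace(cooling, center=(Lx / 2.0, Ly / 2.0), radius=radius)
        probes = tuple(options.pop("probes", ((Lx / 2, Ly / 2),)))
        proto = Protocol(
            name=name, domain=domain, dx=dx, duration=duration, model=model,
            cooling=cooling, probes=probes, dt=dt,
            snapshot_stride=options.pop("snapshot_stride", 30.0),
            s1s2=options.pop("s1s2", S1S2Params()),
        )
    if options:
        raise ValueError(f"unknown protocol options: {sorted(options)}")
    return proto


def run_protocol(
    protocol: Protocol,
    config: SolverConfig | None = None,
    initial_state: FieldState | None = None,
    stop_when=None,
    progress: bool = False,
) -> SimulationResult:
    """Build the grid and initial state for a protocol and integrate it.

    ``initial_state`` short-circuits the builder (useful to reuse one
    initiated spiral across several cooling scenarios, as the study does).
    """
    config = config or SolverConfig(dt=protocol.dt)
    grid = protocol.grid()
    if initial_state is None:
        initial_state = protocol.initial_state(grid, config)
    else:
        initial_state = initial_state.copy()
        T0 = tstar_field(grid, protocol.cooling, 0.0)
        initial_state.T = np.asarray(T0, dtype=float).copy()
    return simulate(
        grid=grid,
        model_spec=protocol.model,
        initial_state=initial_state,
        duration=protocol.duration,
        config=config,
        tissue=protocol.tissue,
        thermal=protocol.thermal,
        tstar_fn=protocol.tstar_fn(grid),
        probes=protocol.probes,
        snapshot_stride=protocol.snapshot_stride,
        stop_when=stop_when,
        progress=progress,
    )
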