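"""Dimensional two-variable ionic kinetics with thermal scaling.

Two phenomenological ventricular models are provided, both rescaled to
physiological millivolt units (rest -85 mV, peak 40 mV):

* Mitchell--Schaeffer (MS): fast cubic inward current gated by a single
  recovery variable W with piecewise-linear opening/closing dynamics.
  Tuned here for a ~1 ms upstroke and ~0.7 m/s conduction at 37 degC.
* Aliev--Panfilov (AP): cubic FitzHugh--Nagumo-type kinetics with a
  voltage-dependent recovery rate, reproducing APD restitution; the
  standard substrate for spiral-wave (reentry) studies.

Temperature enters through two scalar multiplicative factors applied to the
whole ionic current and gating rate,

    I(Vm, W, T) = A (1 + B (T - Ta)) * I_ion(Vm, W)
    F(Vm, W, T) = Q**((T - Ta)/10)  * F_ion(Vm, W)

with reference temperature Ta = 37 degC, so at normothermia the scaled model
is identical to the unscaled one.

Units: potentials mV, times ms, temperatures degC.  With Cm = 1 uF/cm^2 the
ionic "currents" are numerically uA/cm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VoltageScale",
    "MSParams",
    "APParams",
    "ThermoCoupling",
    "CellState",
    "IonicModelSpec",
    "MitchellSchaeffer",
    "AlievPanfilov",
    "make_model",
    "normalized_voltage",
    "thermal_current_factor",
    "thermal_gate_factor",
    "ms_current",
    "ms_gate_rate",
    "ap_current",
    "ap_gate_rate",
    "cell_simulate",
]

AP_TIME_FACTOR = 1.0 / 12.9  # 1/ms; fixed rescaling of the AP recovery rate


@dataclass(frozen=True)
class VoltageScale:
    """Affine map between the dimensionless activation u and Vm (mV)."""

    v_rest: float = -85.0
    v_peak: float = 40.0

    @property
    def v_amp(self) -> float:
        return self.v_peak - self.v_rest

    def __post_init__(self) -> None:
        if self.v_amp <= 0:
            raise ValueError("v_peak must exceed v_rest")


@dataclass(frozen=True)
class MSParams:
    """Mitchell--Schaeffer time constants (ms) and dimensionless gate threshold."""

    tau_in: float = 0.05
    tau_out: float = 1.0
    tau_open: float = 95.0
    tau_close: float = 162.0
    v_gate: float = 0.13

    def __post_init__(self) -> None:
        if min(self.tau_in, self.tau_out, self.tau_open, self.tau_close) <= 0:
            raise ValueError("all MS time constants must be positive")
        if not 0.0 < self.v_gate < 1.0:
            raise ValueError("v_gate must lie in (0, 1)")


@dataclass(frozen=True)
class APParams:
    """Aliev--Panfilov dimensionless parameters.

    The excitation threshold voltage is derived as v_a = v_amp*a + v_rest.
    """

    k: float = 8.0
    a: float = 0.15
    mu1: float = 0.2
    mu2: float = 0.3
    eps0: float = 0.002

    def v_a(self, scale: VoltageScale) -> float:
        return scale.v_amp * self.a + scale.v_rest


@dataclass(frozen=True)
class ThermoCoupling:
    """Scalar thermal coupling: A, B (1/degC) on the current, Q10-type Q on gating."""

    A: float = 1.0
    B: float = 0.07
    Q: float = 2.4
    T_a: float = 37.0

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("Q must be positive")

    @classmethod
    def for_ms(cls) -> "ThermoCoupling":
        return cls(A=1.0, B=0.07, Q=2.4)

    @classmethod
    def for_ap(cls) -> "ThermoCoupling":
        return cls(A=1.0, B=0.081, Q=2.4)


@dataclass
class CellState:
    Vm: float
    W: float
    T: float = 37.0


def normalized_voltage(Vm, scale: VoltageScale):
    """u = (Vm - v_rest)/v_amp; 0 at rest, 1 at peak."""
    return (np.asarray(Vm) - scale.v_rest) / scale.v_amp


def thermal_current_factor(T, tc: ThermoCoupling):
    """A(1 + B(T - Ta)). Warns (does not fail) if the factor is non-positive."""
    f = tc.A * (1.0 + tc.B * (np.asarray(T, dtype=float) - tc.T_a))
    if np.any(f <= 0):
        warnings.warn(
            "thermal current factor <= 0 (T below Ta - 1/B); "
            "model leaves its physical regime",
            RuntimeWarning,
            stacklevel=2,
        )
    return f


def thermal_gate_factor(T, tc: ThermoCoupling):
    """Q**((T - Ta)/10); the classic Q10 rate scaling, equal to 1 at Ta."""
    return tc.Q ** ((np.asarray(T, dtype=float) - tc.T_a) / 10.0)


# ---------------------------------------------------------------------------
# Mitchell--Schaeffer
# ---------------------------------------------------------------------------

def ms_current(Vm, W, p: MSParams, scale: VoltageScale):
    """I_ion = (v_amp/tau_in) W u^2 (u - 1) + (Vm - v_rest)/tau_out.

    The first (inward, depolarizing) term is negative during the upstroke;
    the second is the linear repolarizing current. Both vanish at rest.
    """
    u = normalized_voltage(Vm, scale)
    return (scale.v_amp / p.tau_in) * np.asarray(W) * u * u * (u - 1.0) + (
        scale.v_amp * u / p.tau_out
    )


def ms_gate_rate(Vm, W, p: MSParams, scale: VoltageScale):
    """dW/dt: (1-W)/tau_open below the gate, -W/tau_close at or above it."""
    u = normalized_voltage(Vm, scale)
    W = np.asarray(W)
    return np.where(u < p.v_gate, (1.0 - W) / p.tau_open, -W / p.tau_close)


# ---------------------------------------------------------------------------
# Aliev--Panfilov
# ---------------------------------------------------------------------------

def ap_current(Vm, W, p: APParams, scale: VoltageScale):
    """I_ion = (k/v_amp^2)(Vm-v_rest)(Vm-v_a)(Vm-v_peak) + (Vm-v_rest) W."""
    Vm = np.asarray(Vm)
    va = p.v_a(scale)
    cubic = (p.k / scale.v_amp**2) * (Vm - scale.v_rest) * (Vm - va) * (
        Vm - scale.v_peak
    )
    return cubic + (Vm - scale.v_rest) * np.asarray(W)


def ap_gate_rate(Vm, W, p: APParams, scale: VoltageScale):
    """dW/dt = (1/12.9)(eps0 + mu1 W/(u+mu2)) (-W - k u (u - a - 1))."""
    u = normalized_voltage(Vm, scale)
    W = np.asarray(W)
    denom = u + p.mu2
    if np.any(denom == 0):
        raise ZeroDivisionError("degenerate AP parameterization: u + mu2 = 0")
    eps = p.eps0 + p.mu1 * W / denom
    return AP_TIME_FACTOR * eps * (-W - p.k * u * (u - p.a - 1.0))


# ---------------------------------------------------------------------------
# Model objects: a uniform surface over both kinetics for the PDE solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonicModelSpec:
    """Which kinetics to use, with parameters and thermal coupling constants."""

    kind: str  # "ms" | "ap"
    ms: MSParams = field(default_factory=MSParams)
    ap: APParams = field(default_factory=APParams)
    scale: VoltageScale = field(default_factory=VoltageScale)
    thermo: ThermoCoupling | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ms", "ap"):
            raise ValueError(f"unknown ionic model kind {self.kind!r}")
        if self.thermo is None:
            tc = ThermoCoupling.for_ms() if self.kind == "ms" else ThermoCoupling.for_ap()
            object.__setattr__(self, "thermo", tc)

    def build(self):
        if self.kind == "ms":
            return MitchellSchaeffer(self.ms, self.scale, self.thermo)
        return AlievPanfilov(self.ap, self.scale, self.thermo)

    def with_overrides(self, **kw) -> "IonicModelSpec":
        """Return a spec with parameter overrides applied to the active kinetics."""
        if self.kind == "ms":
            return replace(self, ms=replace(self.ms, **kw))
        return replace(self, ap=replace(self.ap, **kw))


class MitchellSchaeffer:
    """MS kinetics bound to a voltage scale and thermal coupling."""

    kind = "ms"
    rest_W = 1.0

    def __init__(self, p: MSParams, scale: VoltageScale, thermo: ThermoCoupling):
        self.p, self.scale, self.thermo = p, scale, thermo

    def current(self, Vm, W):
        return ms_current(Vm, W, self.p, self.scale)

    def gate_rate(self, Vm, W):
        return ms_gate_rate(Vm, W, self.p, self.scale)

    def d_current_dV(self, Vm, W):
        u = normalized_voltage(Vm, self.scale)
        return (1.0 / self.p.tau_in) * np.asarray(W) * (3.0 * u * u - 2.0 * u) + (
            1.0 / self.p.tau_out
        )

    def d_current_dW(self, Vm, W):
        u = normalized_voltage(Vm, self.scale)
        return (self.scale.v_amp / self.p.tau_in) * u * u * (u - 1.0)

    def solve_gate_bdf(self, Vm, alpha, rhs, theta, W_guess, branch_below=None):
        """Solve alpha*W - theta*F_ion(Vm, W) = rhs for W (exact, branch frozen by Vm).

        Both branches of F_ion are linear in W so the update is closed form.
        ``branch_below`` optionally pins the open/closed branch per node
        (used by the tissue solver to stop branch chattering at nodes that
        sit exactly on the gate within a Newton solve).
        """
        if branch_below is None:
            u = normalized_voltage(Vm, self.scale)
            branch_below = u < self.p.v_gate
        W_open = (rhs + theta / self.p.tau_open) / (alpha + theta / self.p.tau_open)
        W_close = rhs / (alpha + theta / self.p.tau_close)
        return np.where(branch_below, W_open, W_close)

    def gate_branch(self, Vm):
        """Boolean "below gate" mask (the open-branch region) for latching."""
        return normalized_voltage(Vm, self.scale) < self.p.v_gate

    def gate_bdf_dWdV(self, Vm, W, alpha, theta):
        """dW/dV of the implicit gate update; zero a.e. (branch frozen by Vm)."""
        return np.zeros_like(np.asarray(Vm, dtype=float))


class AlievPanfilov:
    """AP kinetics bound to a voltage scale and thermal coupling."""

    kind = "ap"
    rest_W = 0.0

    def __init__(self, p: APParams, scale: VoltageScale, thermo: ThermoCoupling):
        self.p, self.scale, self.thermo = p, scale, thermo

    def current(self, Vm, W):
        return ap_current(Vm, W, self.p, self.scale)

    def gate_rate(self, Vm, W):
        return ap_gate_rate(Vm, W, self.p, self.scale)

    def d_current_dV(self, Vm, W):
        Vm = np.asarray(Vm)
        s, p = self.scale, self.p
        va = p.v_a(s)
        c = p.k / s.v_amp**2
        dcubic = c * (
            (Vm - va) * (Vm - s.v_peak)
            + (Vm - s.v_rest) * (Vm - s.v_peak)
            + (Vm - s.v_rest) * (Vm - va)
        )
        return dcubic + np.asarray(W)

    def d_current_dW(self, Vm, W):
        return np.asarray(Vm) - self.scale.v_rest

    def solve_gate_bdf(self, Vm, alpha, rhs, theta, W_guess, branch_below=None):
        """Solve alpha*W - theta*F_ion(Vm, W) = rhs for W (smooth; branch unused).

        F_ion is quadratic in W, so the BDF update is a per-node quadratic
        a2 W^2 + a1 W + a0 = 0; the root continuous with the theta -> 0 limit
        (W = rhs/alpha) is selected via the numerically stable formula.
        """
        p = self.p
        u = normalized_voltage(Vm, self.scale)
        g = p.k * u * (u - p.a - 1.0)
        c = AP_TIME_FACTOR * np.asarray(theta)
        m = p.mu1 / (u + p.mu2)
        a2 = c * m
        a1 = alpha + c * (p.eps0 + m * g)
        a0 = c * p.eps0 * g - rhs
        disc = a1 * a1 - 4.0 * a2 * a0
        disc = np.maximum(disc, 0.0)
        sq = np.sqrt(disc)
        # a1 > 0 here (alpha dominates); stable smaller-magnitude root:
        q = -0.5 * (a1 + sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(np.abs(a2) > 1e-300, a0 / q, -a0 / a1)
        return W

    def _gate_partials(self, Vm, W, theta):
        """(theta*F_V, theta*F_W) of the scaled gate rate theta*F_ion."""
        p = self.p
        s = self.scale
        u = normalized_voltage(Vm, self.scale)
        W = np.asarray(W)
        c = AP_TIME_FACTOR * np.asarray(theta)
        denom = u + p.mu2
        m = p.mu1 / denom
        g = p.k * u * (u - p.a - 1.0)
        dg = p.k * (2.0 * u - p.a - 1.0)
        eps = p.eps0 + m * W
        F_W = c * (m * (-W - g) - eps)
        F_V = c * (-(m / denom) * W * (-W - g) - eps * dg) / s.v_amp
        return F_V, F_W

    def gate_bdf_dWdV(self, Vm, W, alpha, theta):
        """dW/dV of the implicit gate update alpha*W - theta*F = rhs.

        Implicit-function theorem on the converged W: dW/dV = tF_V/(alpha - tF_W).
        """
        tF_V, tF_W = self._gate_partials(Vm, W, theta)
        return tF_V / (alpha - tF_W)

    def gate_branch(self, Vm):
        """No discontinuous branch in the AP gate; nothing to latch."""
        return None


def make_model(spec: IonicModelSpec):
    return spec.build()


# ---------------------------------------------------------------------------
# 0-D cell integrator (no diffusion) for isolated kinetics testing
# ---------------------------------------------------------------------------

@dataclass
class CellTrace:
    """Uniformly sampled 0-D trajectory."""

    t: np.ndarray  # ms
    Vm: np.ndarray  # mV
    W: np.ndarray
    T: float  # degC, held fixed

    def to_csv(self, path) -> None:
        data = np.column_stack(
            [self.t, self.Vm, self.W, np.full_like(self.t, self.T)]
        )
        np.savetxt(
            path, data, delimiter=",", header="time_ms,Vm_mV,W,T_C", comments=""
        )


class IntegratorError(RuntimeError):
    """Raised when the implicit cell integrator fails to converge."""

    def __init__(self, step: int, residual: float):
        super().__init__(
            f"cell integrator Newton failed at step {step} (|R| = {residual:.3e})"
        )
        self.step = step
        self.residual = residual


def cell_simulate(
    spec: IonicModelSpec,
    T: float,
    init: CellState,
    duration: float,
    dt: float = 0.01,
    Cm: float = 1.0,
) -> CellTrace:
    """Integrate the space-clamped cell Cm dVm/dt = -I(Vm,W,T), dW/dt = F(Vm,W,T).

    BDF2 with one backward-Euler startup step; Newton on Vm with W eliminated
    exactly per step (same strategy as the tissue solver). The MS resting point
    (v_rest, W=1) is an exact fixed point of the discrete scheme.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("require dt > 0 and duration >= dt")
    model = spec.build()
    theta_i = float(thermal_current_factor(T, model.thermo))
    theta_g = float(thermal_gate_factor(T, model.thermo))

    n_steps = int(np.floor(duration / dt))
    t = np.arange(n_steps + 1) * dt
    Vm = np.empty(n_steps + 1)
    W = np.empty(n_steps + 1)
    Vm[0], W[0] = init.Vm, init.W

    v_nm1 = w_nm1 = None
    v_n, w_n = Vm[0], W[0]
    for n in range(n_steps):
        if v_nm1 is None:  # backward-Euler startup
            alpha, beta_v, beta_w = 1.0 / dt, v_n / dt, w_n / dt
        else:
            alpha = 1.5 / dt
            beta_v = (2.0 * v_n - 0.5 * v_nm1) / dt
            beta_w = (2.0 * w_n - 0.5 * w_nm1) / dt
        v = v_n
        converged = False
        res = np.inf
        for _ in range(50):
            w = model.solve_gate_bdf(v, alpha, beta_w, theta_g, w_n)
            res = Cm * (alpha * v - beta_v) + theta_i * model.current(v, w)
            if abs(res) <= 1e-10 * Cm * alpha * model.scale.v_amp:
                converged = True
                break
            jac = Cm * alpha + theta_i * model.d_current_dV(v, w)
            v = v - res / jac
        if not converged:
            raise IntegratorError(n, abs(res))
        v_nm1, w_nm1 = v_n, w_n
        v_n, w_n = float(v), float(model.solve_gate_bdf(v, alpha, beta_w, theta_g, w_n))
        Vm[n + 1], W[n + 1] = v_n, w_n
    return CellTrace(t=t, Vm=Vm, W=W, T=T)
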