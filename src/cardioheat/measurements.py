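"""Quantitative readouts: APD, rise time, conduction velocity, Q10,
termination detection, spiral-tip localization and Joule heat accumulation.

All threshold crossings are located by linear interpolation between samples,
which gives sub-dt resolution (needed e.g. for a ~1 ms upstroke sampled at
0.1 ms).  Default thresholds: APD and activation at -80 mV, upstroke window
-80 to 30 mV, termination (quiescence) at -70 mV, tip isopotential at the
midpoint (v_rest+v_peak)/2 = -22.5 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint
from shapely.geometry import LineString
from skimage import measure as _skmeasure

from .fields_pde import Grid2D

__all__ = [
    "Trace",
    "MeasurementResult",
    "NoActivation",
    "NoRepolarization",
    "apd",
    "rise_time",
    "conduction_velocity",
    "q10",
    "termination_time",
    "tip_locations",
    "heat_accumulation",
]


class NoActivation(ValueError):
    """The trace never exceeds the activation threshold."""


class NoRepolarization(ValueError):
    """The trace is still above threshold at its end."""


@dataclass
class Trace:
    """Vm at a fixed probe on a uniform time axis."""

    x: float  # cm
    y: float  # cm
    t: np.ndarray  # ms, uniform
    Vm: np.ndarray  # mV

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Vm = np.asarray(self.Vm, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.Vm.shape:
            raise ValueError("t and Vm must be matching 1-D arrays")
        dts = np.diff(self.t)
        if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6)):
            raise ValueError("time axis must be strictly increasing and uniform")


@dataclass
class MeasurementResult:
    """One run's scalar readouts, together with the thresholds used."""

    apd_ms: float | None = None
    rise_time_ms: float | None = None
    cv_m_per_s: float | None = None
    q10_apd: float | None = None
    q10_cv: float | None = None
    termination_time_ms: float | None = None
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "apd_ms": self.apd_ms,
            "rise_time_ms": self.rise_time_ms,
            "cv_m_per_s": self.cv_m_per_s,
            "q10_apd": self.q10_apd,
            "q10_cv": self.q10_cv,
            "termination_time_ms": self.termination_time_ms,
            "thresholds": self.thresholds,
        }


def _crossings(t: np.ndarray, v: np.ndarray, level: float, upward: bool) -> np.ndarray:
    """Interpolated times of level crossings in the requested direction."""
    above = v >= level
    if upward:
        idx = np.flatnonzero(~above[:-1] & above[1:])
    else:
        idx = np.flatnonzero(above[:-1] & ~above[1:])
    if idx.size == 0:
        return np.empty(0)
    frac = (level - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def apd(trace: Trace, threshold: float = -80.0, episode: int = 0) -> float:
    """Action potential duration: time Vm stays above ``threshold`` (ms).

    Interpolated down-crossing minus up-crossing of one supra-threshold
    episode (``episode`` selects it when the trace holds several beats).
    """
    up = _crossings(trace.t, trace.Vm, threshold, upward=True)
    if trace.Vm[0] >= threshold:  # already active at trace start
        up = np.concatenate([[trace.t[0]], up])
    if up.size == 0:
        raise NoActivation(f"Vm never exceeds {threshold} mV")
    down = _crossings(trace.t, trace.Vm, threshold, upward=False)
    if episode >= up.size:
        raise IndexError(f"trace has only {up.size} supra-threshold episodes")
    t_up = up[episode]
    later = down[down > t_up]
    if later.size == 0:
        raise NoRepolarization(
            f"Vm still above {threshold} mV at trace end (t_up = {t_up:.2f} ms)"
        )
    return float(later[0] - t_up)


def rise_time(trace: Trace, lo: float = -80.0, hi: float = 30.0) -> float:
    """Upstroke interval between the interpolated lo and hi up-crossings (ms)."""
    t_lo = _crossings(trace.t, trace.Vm, lo, upward=True)
    t_hi = _crossings(trace.t, trace.Vm, hi, upward=True)
    if t_lo.size == 0:
        raise NoActivation(f"Vm never crosses {lo} mV upward")
    if t_hi.size == 0:
        raise NoActivation(f"Vm never crosses {hi} mV upward")
    # pair each lo-crossing with the first subsequent hi-crossing (same upstroke)
    later = t_hi[t_hi >= t_lo[0]]
    if later.size == 0:
        raise NoActivation("no hi crossing after the lo crossing")
    return float(later[0] - t_lo[0])


def activation_time(trace: Trace, threshold: float = -80.0) -> float:
    """First interpolated upward crossing of ``threshold`` (ms)."""
    up = _crossings(trace.t, trace.Vm, threshold, upward=True)
    if up.size == 0:
        raise NoActivation(f"Vm never exceeds {threshold} mV")
    return float(up[0])


def conduction_velocity(
    trace_a: Trace, trace_b: Trace, threshold: float = -80.0
) -> float:
    """Wavefront speed between two probes (m/s): distance / activation delay.

    Probe order is irrelevant; the speed is reported positive.  cm/ms
    converts to m/s by a factor of 10.
    """
    dist = float(np.hypot(trace_a.x - trace_b.x, trace_a.y - trace_b.y))
    if dist == 0:
        raise ValueError("probes coincide")
    dt_act = activation_time(trace_b, threshold) - activation_time(trace_a, threshold)
    if dt_act == 0:
        raise ValueError("zero activation-time difference between probes")
    return abs(dist / dt_act) * 10.0


def q10(
    cold_value: float,
    warm_value: float,
    T_cold: float,
    T_warm: float,
    kind: str,
) -> float:
    """Q10 temperature coefficient for APD- or CV-like quantities.

    APD lengthens on cooling and CV slows, so the two conventions use
    opposite exponent signs and both yield Q10 > 1 for the physiological
    direction:

        Q10(APD) = (cold/warm)**(10/(T_warm - T_cold))
        Q10(CV)  = (cold/warm)**(10/(T_cold - T_warm))
    """
    if cold_value <= 0 or warm_value <= 0:
        raise ValueError("Q10 inputs must be positive")
    if T_warm <= T_cold:
        raise ValueError("require T_warm > T_cold")
    if kind == "apd":
        expo = 10.0 / (T_warm - T_cold)
    elif kind == "cv":
        expo = 10.0 / (T_cold - T_warm)
    else:
        raise ValueError(f"unknown Q10 kind {kind!r}")
    return float((cold_value / warm_value) ** expo)


def termination_time(
    snapshot_times,
    Vm_snapshots,
    threshold: float = -70.0,
):
    """Earliest snapshot time after which max(Vm) stays below ``threshold``.

    Returns None if activity persists through the last snapshot; 0.0 if the
    sequence is quiescent throughout.
    """
    times = np.asarray(list(snapshot_times), dtype=float)
    if times.size == 0:
        raise ValueError("empty snapshot sequence")
    vmax = np.array([np.max(v) for v in Vm_snapshots])
    active = vmax >= threshold
    if active[-1]:
        return None
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return 0.0
    return float(times[idx[-1] + 1])


def _contours(field2d: np.ndarray, level: float):
    return _skmeasure.find_contours(field2d, level)


def tip_locations(
    Vm: np.ndarray,
    Vm_prev: np.ndarray,
    grid: Grid2D,
    iso: float = -22.5,
    merge_radius: float | None = None,
) -> list[tuple[float, float]]:
    """Spiral-tip (phase singularity) positions from two consecutive snapshots.

    A tip is an intersection of the isopotential line Vm = iso with the zero
    isoline of dVm/dt (approximated by Vm - Vm_prev): the only points where
    the activation front and the previous front cross, i.e. where wavefront
    and waveback meet.  Returns an empty list for plane waves.  Nearby
    intersection points (within ``merge_radius``, default 2 grid cells) are
    merged.
    """
    f = Vm - iso
    g = Vm - Vm_prev
    cf = _contours(f, 0.0)
    cg = _contours(g, 0.0)
    if not cf or not cg:
        return []
    pts: list[tuple[float, float]] = []
    lines_g = [LineString(c[:, ::-1]) for c in cg if len(c) >= 2]
    for c in cf:
        if len(c) < 2:
            continue
        lf = LineString(c[:, ::-1])  # (col=x-index, row=y-index)
        for lg in lines_g:
            if not lf.intersects(lg):
                continue
            inter = lf.intersection(lg)
            geoms = getattr(inter, "geoms", [inter])
            for geom in geoms:
                if geom.geom_type == "Point":
                    pts.append((geom.x * grid.dx, geom.y * grid.dy))
                elif geom.geom_type in ("MultiPoint", "LineString"):
                    for p in MultiPoint(list(geom.coords)).geoms:
                        pts.append((p.x * grid.dx, p.y * grid.dy))
    if not pts:
        return []
    if merge_radius is None:
        merge_radius = 2.0 * max(grid.dx, grid.dy)
    clusters: list[list[float]] = []  # [sum_x, sum_y, count]
    for (px, py) in sorted(pts):
        for cl in clusters:
            if np.hypot(cl[0] / cl[2] - px, cl[1] / cl[2] - py) <= merge_radius:
                cl[0] += px
                cl[1] += py
                cl[2] += 1
                break
        else:
            clusters.append([px, py, 1])
    return [(cl[0] / cl[2], cl[1] / cl[2]) for cl in clusters]


def heat_accumulation(
    T: np.ndarray, Tstar: np.ndarray | float, grid: Grid2D
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Joule heat accumulation map dT = T - T*; returns (map, max, argmax xy)."""
    dT = T - np.asarray(Tstar)
    if dT.shape != T.shape:
        raise ValueError("T and Tstar shapes differ")
    j, i = np.unravel_index(np.argmax(dT), dT.shape)
    return dT, float(dT[j, i]), (i * grid.dx, j * grid.dy)
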