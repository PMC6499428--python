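"""Structured-grid spatial operators for the heat--bidomain equations.

Cardiac tissue is modeled as two interpenetrating conductive media
(intra-/extracellular) with axis-aligned diagonal conductivity tensors; the
fiber direction is fixed along x.  This module provides

* the discrete anisotropic diffusion operator div(G grad .) with zero-flux
  (sealed-tissue) boundaries, as a symmetric negative-semidefinite sparse
  matrix whose nullspace is the constants;
* the singular pure-Neumann extracellular solve with mean-zero gauge;
* the Joule (resistive) heating sources feeding Pennes' bioheat equation, in
  both the full intra+extracellular form and the simplified transmembrane
  form G_i grad(Vm) . grad(Vm) used for production runs;
* the equal-anisotropy monodomain reduction of the conductivities.

Unit system: lengths cm, time ms, potential mV, conductivity mS/cm,
temperature degC, volumetric power J/(ms cm^3).  Electrical power
G |grad V|^2 arises in mS mV^2/cm^3 = 1e-12 J/(ms cm^3); JOULE_CONVERSION
is that fixed bridge into the thermal unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Grid2D",
    "Tensor2",
    "TissueParams",
    "ThermalParams",
    "FieldState",
    "JOULE_CONVERSION",
    "divgrad_matrix",
    "anisotropic_divgrad",
    "ExtracellularSolver",
    "solve_extracellular",
    "gradient",
    "joule_source_simplified",
    "joule_source_full",
    "monodomain_conductivity",
    "bioheat_rhs",
]

#: 1 mS mV^2 / cm^3 expressed in J/(ms cm^3)
JOULE_CONVERSION = 1e-12


def factorize(A) -> spla.SuperLU:
    """Sparse LU tuned for our (structurally symmetric) 5-point operators.

    Symmetric-mode ordering roughly halves the fill and the triangular-solve
    cost relative to the default column ordering.
    """
    return spla.splu(
        A.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.001,
        options={"SymmetricMode": True},
    )


@dataclass(frozen=True)
class Grid2D:
    """Uniform node-centered grid on [0, Lx] x [0, Ly]; node (i, j) at (i dx, j dy).

    Fields live on arrays of shape (ny, nx): row index = y, column = x.
    """

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid needs nx, ny >= 3")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings must be positive")

    @classmethod
    def from_extent(cls, Lx: float, Ly: float, dx: float, dy: float | None = None):
        dy = dx if dy is None else dy
        nx = int(round(Lx / dx)) + 1
        ny = int(round(Ly / dy)) + 1
        return cls(nx=nx, ny=ny, dx=dx, dy=dy)

    @property
    def Lx(self) -> float:
        return (self.nx - 1) * self.dx

    @property
    def Ly(self) -> float:
        return (self.ny - 1) * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    @property
    def y(self) -> np.ndarray:
        return np.arange(self.ny) * self.dy

    def meshgrid(self):
        return np.meshgrid(self.x, self.y)

    def node_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the node nearest to physical point (x, y)."""
        i = int(round(x / self.dx))
        j = int(round(y / self.dy))
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise ValueError(f"point ({x}, {y}) outside the domain")
        return j, i


@dataclass(frozen=True)
class Tensor2:
    """Diagonal 2x2 conductivity tensor (mS/cm), axes aligned with the grid."""

    gxx: float
    gyy: float

    def __post_init__(self) -> None:
        if self.gxx <= 0 or self.gyy <= 0:
            raise ValueError("conductivity tensor must be positive definite")

    def __add__(self, other: "Tensor2") -> "Tensor2":
        return Tensor2(self.gxx + other.gxx, self.gyy + other.gyy)

    def scaled(self, s: float) -> "Tensor2":
        return Tensor2(self.gxx * s, self.gyy * s)


@dataclass(frozen=True)
class TissueParams:
    """Bidomain constants: surface-to-volume ratio chi (1/cm), membrane
    capacitance Cm (uF/cm^2), intra/extracellular conductivities (mS/cm)."""

    chi: float = 2000.0
    Cm: float = 1.0
    Gi: Tensor2 = field(default_factory=lambda: Tensor2(3.0, 0.315))
    Ge: Tensor2 = field(default_factory=lambda: Tensor2(2.0, 1.35))


@dataclass(frozen=True)
class ThermalParams:
    """Pennes bioheat constants for perfused myocardium.

    rho: tissue density, kg/cm^3; cp: heat capacity, J/(kg degC);
    kT: thermal conductivity, J/(ms cm degC); bc: perfusion heat-sink
    strength, J/(ms cm^3 degC).  The perfusion relaxation time is
    rho*cp/bc and the equilibrium is T = T* for a source-free tissue.
    """

    rho: float = 1.084e-3
    cp: float = 3676.0
    kT: float = 5.6e-6
    bc: float = 8e-5

    def __post_init__(self) -> None:
        if min(self.rho, self.cp, self.kT, self.bc) <= 0:
            raise ValueError("thermal parameters must be strictly positive")

    @property
    def rho_cp(self) -> float:
        return self.rho * self.cp


@dataclass
class FieldState:
    """The four coupled unknowns on one grid at one time level."""

    Vm: np.ndarray  # mV
    phi_e: np.ndarray  # mV
    W: np.ndarray  # dimensionless
    T: np.ndarray  # degC

    def copy(self) -> "FieldState":
        return FieldState(
            self.Vm.copy(), self.phi_e.copy(), self.W.copy(), self.T.copy()
        )

    def validate(self, grid: Grid2D) -> None:
        for name in ("Vm", "phi_e", "W", "T"):
            arr = getattr(self, name)
            if arr.shape != grid.shape:
                raise ValueError(f"{name} has shape {arr.shape}, grid {grid.shape}")


# ---------------------------------------------------------------------------
# Discrete operators
# ---------------------------------------------------------------------------

def _neumann_1d(n: int, h: float) -> sp.csr_matrix:
    """Symmetric 1-D second difference with zero-flux closure (NSD, nullspace 1)."""
    main = np.full(n, -2.0)
    main[0] = main[-1] = -1.0
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr") / h**2


def divgrad_matrix(g: Tensor2, grid: Grid2D) -> sp.csr_matrix:
    """Sparse matrix of div(g grad .) on flattened (ny, nx) fields.

    Five-point second-order stencil; homogeneous Neumann (zero co-normal
    flux) boundaries.  Symmetric negative semi-definite; annihilates
    constants exactly.
    """
    Dxx = _neumann_1d(grid.nx, grid.dx)
    Dyy = _neumann_1d(grid.ny, grid.dy)
    Ix = sp.identity(grid.nx, format="csr")
    Iy = sp.identity(grid.ny, format="csr")
    return (g.gxx * sp.kron(Iy, Dxx) + g.gyy * sp.kron(Dyy, Ix)).tocsr()


def anisotropic_divgrad(field_arr: np.ndarray, g: Tensor2, grid: Grid2D) -> np.ndarray:
    """Apply div(g grad .) to a field (matrix-free convenience wrapper)."""
    if field_arr.shape != grid.shape:
        raise ValueError(
            f"field shape {field_arr.shape} does not match grid {grid.shape}"
        )
    A = divgrad_matrix(g, grid)
    return (A @ field_arr.ravel()).reshape(grid.shape)


class ExtracellularSolver:
    """Factorized solver for div((Gi+Ge) grad phi_e) = -div(Gi grad Vm).

    The pure-Neumann operator is singular (constants); one node is pinned to
    make the factorization regular and the mean is subtracted afterwards
    (mean-zero gauge).  The right-hand side is discretely compatible because
    the Gi operator annihilates constants.
    """

    def __init__(self, p: TissueParams, grid: Grid2D):
        self.grid = grid
        self.A_i = divgrad_matrix(p.Gi, grid)
        self.A_e = divgrad_matrix(p.Gi + p.Ge, grid)
        A_pin = self.A_e.tolil()
        A_pin[0, :] = 0.0
        A_pin[0, 0] = 1.0
        self._lu = factorize(A_pin)

    def solve(self, Vm: np.ndarray) -> np.ndarray:
        rhs = -(self.A_i @ Vm.ravel())
        rhs[0] = 0.0  # pinned node
        phi = self._lu.solve(rhs)
        phi -= phi.mean()
        return phi.reshape(self.grid.shape)

    def residual(self, Vm: np.ndarray, phi_e: np.ndarray) -> np.ndarray:
        """Unpinned elliptic residual div((Gi+Ge) grad phi_e) + div(Gi grad Vm)."""
        r = self.A_e @ phi_e.ravel() + self.A_i @ Vm.ravel()
        return r.reshape(self.grid.shape)


def solve_extracellular(Vm: np.ndarray, p: TissueParams, grid: Grid2D) -> np.ndarray:
    """One-shot extracellular solve (see ExtracellularSolver for the details)."""
    if not np.all(np.isfinite(Vm)):
        raise ValueError("Vm must be finite")
    return ExtracellularSolver(p, grid).solve(Vm)


def gradient(field_arr: np.ndarray, grid: Grid2D) -> tuple[np.ndarray, np.ndarray]:
    """(d/dx, d/dy) by second-order central differences (one-sided at edges)."""
    dfdy, dfdx = np.gradient(field_arr, grid.dy, grid.dx, edge_order=2)
    return dfdx, dfdy


def joule_source_simplified(
    Vm: np.ndarray, Gi: Tensor2, grid: Grid2D
) -> np.ndarray:
    """Transmembrane Joule source Gi grad(Vm).grad(Vm), in J/(ms cm^3).

    Non-negative quadratic form; the production heat source of the coupled
    model.
    """
    vx, vy = gradient(Vm, grid)
    return JOULE_CONVERSION * (Gi.gxx * vx * vx + Gi.gyy * vy * vy)


def joule_source_full(
    Vm: np.ndarray, phi_e: np.ndarray, p: TissueParams, grid: Grid2D
) -> np.ndarray:
    """Full intra+extracellular Joule source, J/(ms cm^3).

    Gi grad(Vm+phi_e).grad(Vm+phi_e) + Ge grad(phi_e).grad(phi_e); with
    phi_e = 0 it reduces bitwise to the simplified source.
    """
    if Vm.shape != phi_e.shape:
        raise ValueError("Vm and phi_e must share a grid")
    return joule_source_simplified(Vm + phi_e, p.Gi, grid) + joule_source_simplified(
        phi_e, p.Ge, grid
    )


def monodomain_conductivity(Gi: Tensor2, lam: float) -> Tensor2:
    """Equal-anisotropy reduction G = Gi/(1+lam), valid when Gi = lam*Ge."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    return Gi.scaled(1.0 / (1.0 + lam))


def bioheat_rhs(
    T: np.ndarray,
    source: np.ndarray,
    tp: ThermalParams,
    grid: Grid2D,
    Tstar: np.ndarray | float,
) -> np.ndarray:
    """dT/dt = (div(kT grad T) + bc (T* - T) + source)/(rho cp), degC/ms."""
    if T.shape != np.shape(source) and np.shape(source) != ():
        raise ValueError("T and source shapes differ")
    diff = anisotropic_divgrad(T, Tensor2(tp.kT, tp.kT), grid)
    return (diff + tp.bc * (np.asarray(Tstar) - T) + source) / tp.rho_cp
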