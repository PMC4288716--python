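"""Quasi-static mechanical equilibrium by implicit energy descent.

The elastic response of the wall network is assumed much faster than
growth, so between growth increments the tissue sits at a mechanical
equilibrium: nodal forces (elastic + spring + turgor + constraint
reactions) vanish.  We find it by minimizing the total potential

    Pi(x) = W_membrane(x) + U_spring(x) - sum_c P_c V_c(x)

with an implicit gradient step: solve (I - eta K) dx = eta f by conjugate
gradients, where f is the projected force vector and K = df/dx is applied
matrix-free through a central finite difference of the forces.  Large eta
makes the step Newton-like; the step is halved whenever the linear solve
fails, the potential increases, or a triangle degenerates.  Constraints
('fixed' nodes, 'planar' sliding nodes) are enforced by projecting forces,
probe directions and updates, so constrained coordinates are satisfied
exactly at every iterate.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .mechanics import MembraneSet, PressureSet, SpringSet
from .tissue_mesh import BoundaryCondition

__all__ = ["SolverConfig", "EquilibriumResult", "MechanicalState",
           "assemble_forces", "stiffness_action", "implicit_step",
           "solve_equilibrium", "SolverError"]


class SolverError(RuntimeError):
    """Raised when the implicit step cannot make progress."""


@dataclass
class SolverConfig:
    """Numerical parameters of the equilibrium solver.

    eta : implicit step size (time-like); large values approach a Newton
        step.  Adapted internally (halved on rejection, regrown on success).
    force_tol : max-norm residual force at which the state counts as
        equilibrated (force units; scale it to pressure x area of the model).
    max_iters : outer implicit iterations per solve.
    cg_tol / cg_max_iters : relative tolerance and cap for the inner
        conjugate-gradient solve.
    fd_probe : displacement amplitude of the finite-difference stiffness
        probe (length units; ~1e-6 of the geometry scale).
    """

    eta: float = 10.0
    force_tol: float = 1e-6
    max_iters: int = 200
    cg_tol: float = 1e-5
    cg_max_iters: int = 250
    fd_probe: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.eta, self.force_tol, self.max_iters, self.cg_tol,
               self.cg_max_iters, self.fd_probe) <= 0:
            raise ValueError("all solver parameters must be positive")
        if self.cg_tol >= 1:
            raise ValueError("CG relative tolerance must be < 1")


@dataclass
class EquilibriumResult:
    positions: np.ndarray
    residual: float
    iterations: int
    converged: bool
    energy: float


@dataclass
class MechanicalState:
    """Everything the solver needs: geometry, elements, loads, constraints."""

    positions: np.ndarray
    membranes: MembraneSet
    springs: SpringSet
    pressure: PressureSet
    constraints: list[BoundaryCondition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)

    def raw_forces(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        self.membranes.add_forces(x, out)
        self.springs.add_forces(x, out)
        self.pressure.add_forces(x, out)
        return out

    def forces(self, x: np.ndarray) -> np.ndarray:
        """Constraint-projected nodal forces (-grad of the potential on the
        admissible manifold)."""
        return project(self.raw_forces(x), self.constraints)

    def potential(self, x: np.ndarray) -> float:
        return (self.membranes.energy(x) + self.springs.energy(x)
                + self.pressure.potential(x))

    def elastic_energy(self, x: np.ndarray) -> float:
        return self.membranes.energy(x) + self.springs.energy(x)


def project(vec: np.ndarray, constraints: list[BoundaryCondition]) -> np.ndarray:
    """Zero the constrained components of a nodal vector field: all three
    for 'fixed' nodes, the normal component for 'planar' nodes."""
    out = vec.copy()
    for bc in constraints:
        if bc.kind == "fixed":
            out[bc.nodes] = 0.0
        else:
            out[bc.nodes] -= np.outer(out[bc.nodes] @ bc.normal, bc.normal)
    return out


def assemble_forces(state: MechanicalState, x: np.ndarray | None = None) -> np.ndarray:
    """Global projected force vector at the given (default current) positions."""
    return state.forces(state.positions if x is None else x)


def stiffness_action(state: MechanicalState, x: np.ndarray,
                     d: np.ndarray, probe: float) -> np.ndarray:
    """Directional derivative K d = d(force)/dx . d, via a central finite
    difference over a probe displacement of fixed physical amplitude."""
    nd = np.linalg.norm(d)
    if nd == 0:
        return np.zeros_like(d)
    u = project(d / nd, [])  # d is already projected by callers
    h = probe
    fp = state.forces(x + h * u)
    fm = state.forces(x - h * u)
    return (nd / (2.0 * h)) * (fp - fm)


def _degenerate(state: MechanicalState, x: np.ndarray) -> bool:
    if not len(state.membranes):
        return False
    return bool(np.any(state.membranes.current_areas(x)
                       < 1e-8 * state.membranes.rest_area))


def implicit_step(state: MechanicalState, config: SolverConfig,
                  x: np.ndarray | None = None, eta: float | None = None
                  ) -> tuple[np.ndarray, float]:
    """One implicit descent step: solve (I - eta K) dx = eta f and apply it.

    Returns (new positions, eta actually used).  eta is halved (down to a
    floor of eta/2^20) whenever CG fails, the potential increases, or the
    update collapses a triangle; if no admissible step exists a SolverError
    is raised.
    """
    if x is None:
        x = state.positions
    eta0 = config.eta if eta is None else eta
    f = state.forces(x)
    if not np.any(f):
        return x.copy(), eta0
    pi0 = state.potential(x)
    shape = x.shape
    n = x.size
    eta_try = eta0
    for _ in range(21):
        def matvec(v, _eta=eta_try):
            dv = project(np.asarray(v, float).reshape(shape), state.constraints)
            kd = stiffness_action(state, x, dv, config.fd_probe)
            return (dv - _eta * kd).ravel()

        A = LinearOperator((n, n), matvec=matvec, dtype=float)
        dx, info = cg(A, (eta_try * f).ravel(), rtol=config.cg_tol,
                      maxiter=config.cg_max_iters)
        if info == 0:
            dx = project(dx.reshape(shape), state.constraints)
            x_new = x + dx
            if not _degenerate(state, x_new):
                pi1 = state.potential(x_new)
                if pi1 <= pi0 + 1e-12 * (abs(pi0) + 1.0):
                    return x_new, eta_try
        eta_try *= 0.5
        if eta_try < eta0 / 2 ** 20:
            break
    raise SolverError("implicit step failed: no admissible step size found")


def solve_equilibrium(state: MechanicalState, config: SolverConfig
                      ) -> EquilibriumResult:
    """Iterate implicit steps until the projected residual force max-norm
    drops below force_tol (or max_iters is hit).  Updates state.positions
    in place and reports diagnostics."""
    x = state.positions.copy()
    eta = config.eta
    it = 0
    res = float(np.abs(state.forces(x)).max()) if x.size else 0.0
    while res > config.force_tol and it < config.max_iters:
        x, eta_used = implicit_step(state, config, x, eta)
        # regrow the step after success, but keep memory of halvings
        eta = min(config.eta, eta_used * 2.0)
        res = float(np.abs(state.forces(x)).max())
        it += 1
    state.positions = x
    return EquilibriumResult(positions=x, residual=res, iterations=it,
                             converged=bool(res <= config.force_tol),
                             energy=state.elastic_energy(x))
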