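"""Elastic constitutive model and force computation.

Cell walls are modeled as thickness-integrated membranes: outer (periclinal)
walls carry orthotropic St-Venant triangle elements, inner walls carry 1D
springs between cell vertices plus massless pressure-bearing faces so that
turgor differences between neighboring cells transmit load.  Strain is the
Green-Lagrange tensor of the elastic deformation from each element's own
rest ("grown") configuration; stress follows Hooke's law with a diagonal
Voigt stiffness (two Young's moduli and a shear modulus, null Poisson
coupling).  Moduli have units of force/length (wall thickness integrated
into the in-plane properties), pressures force/area, lengths are model
units.

Each triangle element stores its rest geometry as a 2x2 edge matrix R whose
columns are the rest edge vectors expressed in the element's material frame
(stiff axis x, orthogonal y).  The elastic deformation gradient is the 3x2
map F = D R^-1 with D the current edge vectors; growth evolves R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrthotropicMaterial",
    "TriangleElement",
    "SpringElement",
    "MembraneSet",
    "SpringSet",
    "PressureSet",
    "elastic_deformation_gradient",
    "green_lagrange",
    "stress",
    "energy_density",
    "triangle_nodal_forces",
    "spring_force",
    "pressure_nodal_forces",
    "effective_pressures",
    "material_frame",
]


class ElementError(ValueError):
    """Raised for degenerate or inconsistent element states."""


@dataclass
class OrthotropicMaterial:
    """Thickness-integrated orthotropic membrane (force/length moduli)."""

    Ex: float
    Ey: float
    G: float

    def __post_init__(self) -> None:
        if min(self.Ex, self.Ey, self.G) <= 0:
            raise ElementError("moduli must be positive")


def material_frame(e1: np.ndarray, e2: np.ndarray,
                   stiff_dir: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal in-plane frame (x_hat, y_hat, n_hat) for a triangle.

    x_hat is the stiff material axis: the in-plane projection of
    ``stiff_dir`` when given, else the direction of the first edge.
    """
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn < 1e-300:
        raise ElementError("degenerate triangle (zero area)")
    n_hat = n / nn
    d = e1 if stiff_dir is None else np.asarray(stiff_dir, float)
    x = d - (d @ n_hat) * n_hat
    if np.linalg.norm(x) < 1e-8 * np.linalg.norm(d):
        x = e1 - (e1 @ n_hat) * n_hat  # stiff axis ~ normal: fall back
    x_hat = x / np.linalg.norm(x)
    return x_hat, np.cross(n_hat, x_hat), n_hat


def rest_edge_matrix(positions: np.ndarray, nodes, stiff_dir=None) -> np.ndarray:
    """2x2 rest edge matrix of a triangle in its material frame (det > 0)."""
    x0, x1, x2 = (np.asarray(positions, float)[list(nodes)])
    e1, e2 = x1 - x0, x2 - x0
    x_hat, y_hat, _ = material_frame(e1, e2, stiff_dir)
    return np.array([[x_hat @ e1, x_hat @ e2],
                     [y_hat @ e1, y_hat @ e2]])


@dataclass
class TriangleElement:
    """One anisotropic membrane triangle (a patch of an outer wall)."""

    nodes: tuple[int, int, int]
    R: np.ndarray                       # 2x2 rest edge matrix, material frame
    material: OrthotropicMaterial
    pressure: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float).reshape(2, 2)
        if np.linalg.det(self.R) <= 0:
            raise ElementError("rest edge matrix must have positive determinant")

    @classmethod
    def from_positions(cls, nodes, positions, material,
                       stiff_dir=None, pressure=0.0) -> "TriangleElement":
        return cls(tuple(nodes), rest_edge_matrix(positions, nodes, stiff_dir),
                   material, pressure)

    @property
    def rest_area(self) -> float:
        return 0.5 * float(np.linalg.det(self.R))


@dataclass
class SpringElement:
    """1D elasto-plastic inner-wall element between two cell vertices.

    Force magnitude k (l - l0)/l0 along the edge: strain-normalized so the
    stiffness k (force units) is unchanged by growth of the rest length l0.
    """

    nodes: tuple[int, int]
    k: float
    l0: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.l0 <= 0:
            raise ElementError("spring stiffness and rest length must be positive")


# -- scalar constitutive operations ----------------------------------------

def elastic_deformation_gradient(element: TriangleElement,
                                 positions: np.ndarray) -> np.ndarray:
    """3x2 elastic deformation gradient F = D R^-1 mapping rest material
    coordinates to current space (uniform over the triangle)."""
    x = np.asarray(positions, float)
    i, j, k = element.nodes
    D = np.stack([x[j] - x[i], x[k] - x[i]], axis=1)
    return D @ np.linalg.inv(element.R)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I)/2 (2x2, material frame)."""
    return 0.5 * (F.T @ F - np.eye(2))


def stress(E: np.ndarray, material: OrthotropicMaterial) -> np.ndarray:
    """Second Piola-Kirchhoff stress from the diagonal Voigt law:
    (Sxx, Syy, Sxy) = (Ex Exx, Ey Eyy, G * 2 Exy)."""
    sxy = material.G * (E[0, 1] + E[1, 0])
    return np.array([[material.Ex * E[0, 0], sxy],
                     [sxy, material.Ey * E[1, 1]]])


def energy_density(E: np.ndarray, material: OrthotropicMaterial) -> float:
    """Elastic energy per unit rest area, W = 1/2 E:C:E >= 0."""
    return 0.5 * (material.Ex * E[0, 0] ** 2 + material.Ey * E[1, 1] ** 2
                  + material.G * (E[0, 1] + E[1, 0]) ** 2)


def triangle_nodal_forces(element: TriangleElement,
                          positions: np.ndarray) -> np.ndarray:
    """Elastic nodal forces f_i = -d(A W)/dx_i (3x3 array, rows per node).

    The three forces sum to zero and exert no net torque: the element energy
    is rigid-motion invariant."""
    F = elastic_deformation_gradient(element, positions)
    S = stress(green_lagrange(F), element.material)
    G = element.rest_area * (F @ S) @ np.linalg.inv(element.R).T
    f1, f2 = -G[:, 0], -G[:, 1]
    return np.stack([-(f1 + f2), f1, f2])


def spring_force(element: SpringElement, positions: np.ndarray) -> np.ndarray:
    """Force pair (2x3): equal and opposite, attractive when stretched."""
    x = np.asarray(positions, float)
    i, j = element.nodes
    d = x[j] - x[i]
    l = np.linalg.norm(d)
    if l < 1e-300:
        raise ElementError("coincident spring nodes")
    f = element.k * (l - element.l0) / element.l0 * (d / l)
    return np.stack([f, -f])


def pressure_nodal_forces(triangles: np.ndarray, pressures: np.ndarray,
                          positions: np.ndarray) -> np.ndarray:
    """Lump turgor pressure onto nodes: each node of triangle t receives
    P_t A_t n_t / 3 with current area and right-hand (outward) normal."""
    x = np.asarray(positions, float)
    t = np.asarray(triangles, int).reshape(-1, 3)
    p = np.broadcast_to(np.asarray(pressures, float), len(t))
    An = 0.5 * np.cross(x[t[:, 1]] - x[t[:, 0]], x[t[:, 2]] - x[t[:, 0]])
    contrib = (p[:, None] * An) / 3.0
    out = np.zeros_like(x)
    for c in range(3):
        np.add.at(out, t[:, c], contrib)
    return out


def effective_pressures(mesh, cell_pressures: np.ndarray) -> np.ndarray:
    """Signed net pressure per wall, along the wall's stored orientation.

    Outer walls carry the adjacent cell's pressure (outside is at zero);
    inner walls carry the difference P_low - P_high of the lower-index minus
    higher-index adjacent cell, so uniform turgor puts zero net load on
    every inner wall.
    """
    p = np.asarray(cell_pressures, float)
    out = np.empty(len(mesh.walls))
    for wi, adj in enumerate(mesh.wall_cells):
        out[wi] = p[adj[0]] - (p[adj[1]] if len(adj) == 2 else 0.0)
    return out


# -- vectorized element sets ------------------------------------------------

class MembraneSet:
    """Batch of triangle membrane elements operated on as numpy arrays."""

    def __init__(self, nodes: np.ndarray, R: np.ndarray,
                 Ex: np.ndarray, Ey: np.ndarray, G: np.ndarray):
        self.nodes = np.asarray(nodes, int).reshape(-1, 3)
        n = len(self.nodes)
        self.Ex = np.broadcast_to(np.asarray(Ex, float), n).copy()
        self.Ey = np.broadcast_to(np.asarray(Ey, float), n).copy()
        self.G = np.broadcast_to(np.asarray(G, float), n).copy()
        self.set_rest(np.asarray(R, float).reshape(-1, 2, 2))

    def __len__(self) -> int:
        return len(self.nodes)

    def set_rest(self, R: np.ndarray) -> None:
        det = R[:, 0, 0] * R[:, 1, 1] - R[:, 0, 1] * R[:, 1, 0]
        if len(det) and np.any(det <= 0):
            raise ElementError("rest edge matrices must have positive determinant")
        self.R = R
        self.Rinv = np.linalg.inv(R) if len(R) else R.copy()
        self.rest_area = 0.5 * det

    @classmethod
    def from_triangles(cls, positions, tris, stiff_dirs, Ex, Ey, G) -> "MembraneSet":
        tris = np.asarray(tris, int).reshape(-1, 3)
        n = len(tris)
        R = np.empty((n, 2, 2))
        dirs = None if stiff_dirs is None else np.asarray(stiff_dirs, float)
        for t in range(n):
            R[t] = rest_edge_matrix(positions, tris[t],
                                    None if dirs is None else dirs[t])
        return cls(tris, R, Ex, Ey, G)

    def deformation(self, x: np.ndarray) -> np.ndarray:
        """(T,3,2) elastic deformation gradients."""
        D = np.stack([x[self.nodes[:, 1]] - x[self.nodes[:, 0]],
                      x[self.nodes[:, 2]] - x[self.nodes[:, 0]]], axis=2)
        return D @ self.Rinv

    def strains(self, x: np.ndarray) -> np.ndarray:
        F = self.deformation(x)
        C = np.einsum("tki,tkj->tij", F, F)
        C[:, 0, 0] -= 1.0
        C[:, 1, 1] -= 1.0
        return 0.5 * C

    def stresses(self, E: np.ndarray) -> np.ndarray:
        S = np.empty_like(E)
        S[:, 0, 0] = self.Ex * E[:, 0, 0]
        S[:, 1, 1] = self.Ey * E[:, 1, 1]
        S[:, 0, 1] = S[:, 1, 0] = self.G * (E[:, 0, 1] + E[:, 1, 0])
        return S

    def energy(self, x: np.ndarray) -> float:
        E = self.strains(x)
        W = 0.5 * (self.Ex * E[:, 0, 0] ** 2 + self.Ey * E[:, 1, 1] ** 2
                   + self.G * (2.0 * E[:, 0, 1]) ** 2)
        return float(self.rest_area @ W)

    def current_areas(self, x: np.ndarray) -> np.ndarray:
        e1 = x[self.nodes[:, 1]] - x[self.nodes[:, 0]]
        e2 = x[self.nodes[:, 2]] - x[self.nodes[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    def add_forces(self, x: np.ndarray, out: np.ndarray) -> None:
        if not len(self.nodes):
            return
        F = self.deformation(x)
        S = self.stresses(self.strains(x))
        G3 = self.rest_area[:, None, None] * np.einsum(
            "tik,tkl,tjl->tij", F, S, self.Rinv)
        f1 = -G3[:, :, 0]
        f2 = -G3[:, :, 1]
        np.add.at(out, self.nodes[:, 0], -(f1 + f2))
        np.add.at(out, self.nodes[:, 1], f1)
        np.add.at(out, self.nodes[:, 2], f2)


class SpringSet:
    """Batch of inner-wall springs."""

    def __init__(self, nodes: np.ndarray, k: np.ndarray, l0: np.ndarray):
        self.nodes = np.asarray(nodes, int).reshape(-1, 2)
        n = len(self.nodes)
        self.k = np.broadcast_to(np.asarray(k, float), n).copy()
        self.l0 = np.broadcast_to(np.asarray(l0, float), n).copy()
        if n and (np.any(self.k <= 0) or np.any(self.l0 <= 0)):
            raise ElementError("spring stiffness and rest length must be positive")

    def __len__(self) -> int:
        return len(self.nodes)

    def lengths(self, x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(x[self.nodes[:, 1]] - x[self.nodes[:, 0]], axis=1)

    def strains(self, x: np.ndarray) -> np.ndarray:
        return (self.lengths(x) - self.l0) / self.l0

    def energy(self, x: np.ndarray) -> float:
        if not len(self.l0):
            return 0.0
        eps = self.strains(x)
        return float(np.sum(0.5 * self.k * self.l0 * eps ** 2))

    def add_forces(self, x: np.ndarray, out: np.ndarray) -> None:
        if not len(self.l0):
            return
        d = x[self.nodes[:, 1]] - x[self.nodes[:, 0]]
        l = np.linalg.norm(d, axis=1)
        f = (self.k * (l - self.l0) / (self.l0 * l))[:, None] * d
        np.add.at(out, self.nodes[:, 0], f)
        np.add.at(out, self.nodes[:, 1], -f)


class PressureSet:
    """Pressure-bearing oriented triangles with signed net pressure.

    Triangles cover the full wall triangulation of the tissue; ``values``
    holds the effective (difference) pressure along each triangle's stored
    orientation.  For closed cells the nodal forces are exactly the gradient
    of the pressure potential -sum_c P_c V_c.
    """

    def __init__(self, triangles: np.ndarray, values: np.ndarray):
        self.triangles = np.asarray(triangles, int).reshape(-1, 3)
        self.values = np.broadcast_to(np.asarray(values, float),
                                      len(self.triangles)).copy()

    def __len__(self) -> int:
        return len(self.triangles)

    def add_forces(self, x: np.ndarray, out: np.ndarray) -> None:
        if not len(self.triangles) or not np.any(self.values):
            return
        out += pressure_nodal_forces(self.triangles, self.values, x)

    def potential(self, x: np.ndarray) -> float:
        """-sum_t P_t (signed cone volume of t); equals -sum_c P_c V_c on
        closed tissues."""
        if not len(self.triangles) or not np.any(self.values):
            return 0.0
        t = self.triangles
        vol6 = np.einsum("ij,ij->i", x[t[:, 0]],
                         np.cross(x[t[:, 1]], x[t[:, 2]]))
        return float(-(self.values @ vol6) / 6.0)
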