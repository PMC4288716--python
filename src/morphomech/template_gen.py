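"""Procedural synthetic tissue templates.

The central template is a layered hemispherical dome of polyhedral cells
standing on a flat base, emulating a shoot apical meristem: an outermost
shell of epidermis-like (L1) cells over one or more inner shells and a core
cell.  Geometry is a spherical lattice — ``resolution`` azimuthal sectors,
a derived number of polar bands (apex cap included) and ``layers`` radial
shells — so cell counts and shapes are fully reproducible.  Region labels
(central zone, periphery, primordium, frontier, adaxial/abaxial, ...) are
assigned by geometric predicates, and per-triangle anisotropy direction
fields encode cortical-microtubule-like orientation of the stiff material
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue_mesh import BoundaryCondition, TissueMesh, Triangulation

__all__ = [
    "DomeSpec",
    "RegionSpec",
    "AnisotropyField",
    "build_dome",
    "build_icosphere",
    "assign_regions",
    "circumferential_direction",
    "anisotropy_gradient",
]


@dataclass
class DomeSpec:
    """Geometry of the synthetic meristem dome.

    radius : base radius of the hemisphere (model units).
    layers : number of radial cell shells outside the core (>= 2 so that an
        L1 shell and at least one inner shell exist).
    resolution : azimuthal cells per ring (>= 4); the number of polar bands
        is resolution/4 rounded, keeping cells roughly isotropic in shape.
    jitter / seed : optional relative vertex perturbation to break the
        rotational symmetry, seeded for reproducibility (default off).
    """

    radius: float = 1.0
    layers: int = 3
    resolution: int = 16
    jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.layers < 2:
            raise ValueError("need at least 2 cell layers")
        if self.resolution < 4:
            raise ValueError("angular resolution must be >= 4")

    @property
    def bands(self) -> int:
        # one extra, half-width apex band keeps facet sizes (and hence the
        # discrete membrane response) uniform up to the pole
        return max(2, int(round(self.resolution / 4)) + 1)


def _wall_points_out(verts: np.ndarray, wall: np.ndarray, inside: np.ndarray) -> bool:
    """True if the wall's right-hand normal points away from ``inside``."""
    p = verts[wall]
    # Newell normal: robust for mildly non-planar polygons
    n = np.cross(p, np.roll(p, -1, axis=0)).sum(axis=0)
    return float(n @ (p.mean(axis=0) - inside)) > 0


def build_dome(spec: DomeSpec) -> TissueMesh:
    """Build the layered hemispherical dome template.

    The outermost shell of cells is labeled 'L1' and everything else 'inner';
    basal nodes carry a planar constraint (free to slide in the base plane).
    """
    R, L, n, m = spec.radius, spec.layers, spec.resolution, spec.bands
    radii = R * (np.arange(L + 1) + 1.0) / (L + 1.0)
    # half-width apex band: the apex cap subtends half a regular band, so
    # its fan triangles stay comparable in size to the ring quads
    thetas = np.pi / 2 * np.concatenate(
        [[0.0], np.arange(m) + 0.5]) / (m - 0.5)
    phis = 2 * np.pi * np.arange(n) / n

    block = 1 + m * n  # vertices per radius: apex + m rings of n

    def apex(k):
        return k * block

    def pid(k, j, i):
        return k * block + 1 + (j - 1) * n + (i % n)

    verts = np.empty(((L + 1) * block, 3))
    for k, r in enumerate(radii):
        verts[apex(k)] = (0.0, 0.0, r)
        for j in range(1, m + 1):
            st, ct = np.sin(thetas[j]), np.cos(thetas[j])
            verts[pid(k, j, 0):pid(k, j, 0) + n] = np.stack(
                [r * st * np.cos(phis), r * st * np.sin(phis),
                 np.full(n, r * ct)], axis=1)
    # clamp the base ring exactly onto z = 0
    for k in range(L + 1):
        verts[pid(k, m, 0):pid(k, m, 0) + n, 2] = 0.0

    walls: list[list[int]] = []
    widx: dict[tuple, int] = {}

    def add(key, cycle) -> int:
        widx[key] = len(walls)
        walls.append(list(cycle))
        return widx[key]

    # spherical surface walls at every radius
    for k in range(L + 1):
        for i in range(n):
            add(("cap", k, i), [apex(k), pid(k, 1, i), pid(k, 1, i + 1)])
        for b in range(1, m):
            for i in range(n):
                add(("sph", k, b, i),
                    [pid(k, b, i), pid(k, b, i + 1),
                     pid(k, b + 1, i + 1), pid(k, b + 1, i)])
    # radial walls (constant phi) between azimuthal sectors
    for k in range(L):
        for b in range(1, m):
            for i in range(n):
                add(("rad", k, b, i),
                    [pid(k, b, i), pid(k, b + 1, i),
                     pid(k + 1, b + 1, i), pid(k + 1, b, i)])
    # latitude walls (constant theta) between polar bands
    for k in range(L):
        for j in range(1, m):
            for i in range(n):
                add(("lat", k, j, i),
                    [pid(k, j, i), pid(k, j, i + 1),
                     pid(k + 1, j, i + 1), pid(k + 1, j, i)])
    # base annulus walls and the core base disk
    for k in range(L):
        for i in range(n):
            add(("base", k, i),
                [pid(k, m, i), pid(k, m, i + 1),
                 pid(k + 1, m, i + 1), pid(k + 1, m, i)])
    add(("disk",), [pid(0, m, i) for i in range(n)])

    cells: list[list[int]] = []
    layer: list[int] = []
    # core cell: inner sphere surface + base disk
    core = [widx[("cap", 0, i)] for i in range(n)]
    core += [widx[("sph", 0, b, i)] for b in range(1, m) for i in range(n)]
    core.append(widx[("disk",)])
    cells.append(core)
    layer.append(0)
    for k in range(L):
        cap = [widx[("cap", k, i)] for i in range(n)]
        cap += [widx[("cap", k + 1, i)] for i in range(n)]
        cap += [widx[("lat", k, 1, i)] for i in range(n)]
        cells.append(cap)
        layer.append(k + 1)
        for b in range(1, m):
            for i in range(n):
                c = [widx[("sph", k, b, i)], widx[("sph", k + 1, b, i)],
                     widx[("rad", k, b, i)], widx[("rad", k, b, (i + 1) % n)],
                     widx[("lat", k, b, i)]]
                c.append(widx[("base", k, i)] if b == m - 1
                         else widx[("lat", k, b + 1, i)])
                cells.append(c)
                layer.append(k + 1)

    mesh = TissueMesh(verts, walls, cells, cell_layer=np.asarray(layer))

    # enforce the orientation convention: outer walls wind out of the tissue,
    # inner walls out of their lower-index adjacent cell.  Decided on the
    # regular lattice, before any jitter, so it is purely topological.
    centroids = [np.mean(verts[np.unique(np.concatenate(
        [mesh.walls[w] for w in cell]))], axis=0) for cell in mesh.cells]
    for wi, adj in enumerate(mesh.wall_cells):
        inside = centroids[adj[0]]
        if not _wall_points_out(verts, mesh.walls[wi], inside):
            mesh.walls[wi] = mesh.walls[wi][::-1]

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        scale = spec.jitter * R * (np.pi / 2) / m
        d = rng.uniform(-scale, scale, size=verts.shape)
        d[np.abs(verts[:, 2]) < 1e-12, 2] = 0.0  # basal nodes stay planar
        d[[apex(k) for k in range(L + 1)]] = 0.0
        verts = verts + d
        mesh.vertices = verts

    basal = np.flatnonzero(np.abs(verts[:, 2]) < 1e-12)
    mesh.boundary = [BoundaryCondition(basal, "planar", np.array([0.0, 0.0, 1.0]))]
    outermost = L
    mesh.region_labels = {ci: ("L1" if layer[ci] == outermost else "inner")
                          for ci in range(len(cells))}
    return mesh


def build_icosphere(radius: float = 1.0, subdivisions: int = 2) -> TissueMesh:
    """Single-cell triangulated sphere (geodesic icosahedron), used as the
    minimal closed pressurized template."""
    t = (1 + np.sqrt(5)) / 2
    v = np.array([[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
                  [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
                  [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], float)
    f = [(0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
         (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
         (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
         (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    verts = list(v / np.linalg.norm(v[0]))
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def mid(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                p = verts[a] + verts[b]
                verts.append(p / np.linalg.norm(p))
                cache[key] = len(verts) - 1
            return cache[key]

        f = [tri for (a, b, c) in f
             for tri in ((a, mid(a, b), mid(c, a)),
                         (b, mid(b, c), mid(a, b)),
                         (c, mid(c, a), mid(b, c)),
                         (mid(a, b), mid(b, c), mid(c, a)))]
    verts = radius * np.asarray(verts)
    walls = [list(tri) for tri in f]
    mesh = TissueMesh(verts, walls, [list(range(len(walls)))],
                      region_labels={0: "L1"})
    for wi, w in enumerate(mesh.walls):
        if not _wall_points_out(verts, w, np.zeros(3)):
            mesh.walls[wi] = w[::-1]
    return mesh


# -- region labeling -------------------------------------------------------

@dataclass
class RegionSpec:
    """Geometric predicate selecting cells for one region label.

    kind 'height_band' selects by centroid height fraction in [lo, hi]
    (measured from the base plane to the apex); 'cap' selects a spherical cap
    of half-angle ``angle`` around the direction ``center`` (optionally only
    its 'adaxial' — apex-facing — or 'abaxial' half); 'ring' selects the
    annulus between two cap angles.  ``layers`` optionally restricts the
    predicate to given radial shells (e.g. inner cells only).  Specs are
    applied in priority order: the first matching spec labels the cell.
    """

    name: str
    kind: str                       # 'height_band' | 'cap' | 'ring' | 'all'
    lo: float = 0.0
    hi: float = 1.0
    center: np.ndarray | None = None
    angle: float = 0.0
    inner_angle: float = 0.0
    side: str | None = None         # None | 'adaxial' | 'abaxial'
    layers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.center is not None:
            c = np.asarray(self.center, float)
            self.center = c / np.linalg.norm(c)


def _cell_centroids(mesh: TissueMesh) -> np.ndarray:
    return np.stack([
        mesh.vertices[np.unique(np.concatenate(
            [mesh.walls[w] for w in cell]))].mean(axis=0)
        for cell in mesh.cells])


def _matches(spec: RegionSpec, c: np.ndarray, apex_h: float,
             layer: int | None) -> bool:
    if spec.layers is not None and layer not in spec.layers:
        return False
    if spec.kind == "all":
        return True
    if spec.kind == "height_band":
        h = c[2] / apex_h
        return spec.lo - 1e-12 <= h <= spec.hi + 1e-12
    r = np.linalg.norm(c)
    if r == 0:
        return False
    ang = np.arccos(np.clip(c / r @ spec.center, -1, 1))
    if spec.kind == "cap":
        if ang > spec.angle:
            return False
        if spec.side is None:
            return True
        # adaxial = apex-facing half of the cap (smaller polar angle than
        # the cap center), abaxial = base-facing half
        pol_c = np.arccos(np.clip(spec.center[2], -1, 1))
        pol = np.arccos(np.clip(c[2] / r, -1, 1))
        return pol <= pol_c if spec.side == "adaxial" else pol > pol_c
    if spec.kind == "ring":
        return spec.inner_angle < ang <= spec.angle
    raise ValueError(f"unknown region kind {spec.kind!r}")


def assign_regions(mesh: TissueMesh, specs: list[RegionSpec],
                   default: str = "Pe") -> dict[int, str]:
    """Label every cell with the first matching spec (priority order);
    unmatched cells get the default label.  Empty regions only warn."""
    import warnings

    cents = _cell_centroids(mesh)
    apex_h = float(mesh.vertices[:, 2].max())
    labels: dict[int, str] = {}
    hit = {s.name: 0 for s in specs}
    for ci, c in enumerate(cents):
        layer = int(mesh.cell_layer[ci]) if mesh.cell_layer is not None else None
        labels[ci] = default
        for s in specs:
            if _matches(s, c, apex_h, layer):
                labels[ci] = s.name
                hit[s.name] += 1
                break
    for name, cnt in hit.items():
        if cnt == 0:
            warnings.warn(f"region {name!r} matched no cells", stacklevel=2)
    return labels


# -- anisotropy direction fields -------------------------------------------

def circumferential_direction(point: np.ndarray, axis: np.ndarray,
                              normal: np.ndarray | None = None) -> np.ndarray:
    """Unit direction tangent to the circle around ``axis`` through ``point``.

    With ``axis`` the dome axis this is the hoop (circumferential) direction;
    with ``axis`` pointing through a primordium center it is the ortho-radial
    direction around that organ.  If a surface ``normal`` is given the result
    is additionally projected into the tangent plane and renormalized.
    """
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    d = np.cross(a, np.asarray(point, float))
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("circumferential direction undefined on the axis")
    d = d / nd
    if normal is not None:
        nrm = np.asarray(normal, float)
        nrm = nrm / np.linalg.norm(nrm)
        d = d - (d @ nrm) * nrm
        nd = np.linalg.norm(d)
        if nd < 1e-8:
            raise ValueError("direction degenerate after tangent projection")
        d = d / nd
    return d


def anisotropy_gradient(mesh: TissueMesh, tri: Triangulation,
                        bottom: float, top: float,
                        positions: np.ndarray | None = None) -> np.ndarray:
    """Per-triangle stiffness ratio interpolated linearly in height fraction
    between ``bottom`` (base plane) and ``top`` (apex)."""
    if bottom < 1 or top < 1:
        raise ValueError("stiffness ratios must be >= 1")
    x = mesh.vertices if positions is None else positions
    cz = x[tri.triangles].mean(axis=1)[:, 2]
    h = np.clip(cz / x[:, 2].max(), 0.0, 1.0)
    return bottom + (top - bottom) * h


@dataclass
class AnisotropyField:
    """Stiff-axis direction field for membrane triangles.

    mode 'isotropic' leaves the material direction arbitrary;
    'circumferential' uses the hoop direction about ``axis``;
    'ortho-radial' uses circles about the axis through ``center``;
    'gradient' is circumferential with a height-interpolated ratio
    (bottom_ratio at the base to top_ratio at the apex).
    """

    mode: str = "isotropic"
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray | None = None
    ratio: float = 1.0
    bottom_ratio: float = 1.0
    top_ratio: float = 1.0

    def directions(self, centroids: np.ndarray, normals: np.ndarray) -> np.ndarray:
        """Unit tangent stiff-axis per triangle (any tangent if isotropic)."""
        out = np.empty_like(centroids)
        ax = self.center if self.mode == "ortho-radial" else self.axis
        for i, (c, nrm) in enumerate(zip(centroids, normals)):
            if self.mode == "isotropic":
                t = np.cross(nrm, [1.0, 0.0, 0.0])
                if np.linalg.norm(t) < 1e-6:
                    t = np.cross(nrm, [0.0, 1.0, 0.0])
                out[i] = t / np.linalg.norm(t)
            else:
                out[i] = circumferential_direction(c, ax, nrm)
        return out

    def ratios(self, mesh: TissueMesh, tri: Triangulation,
               subset: np.ndarray | None = None) -> np.ndarray:
        """Per-triangle stiff/soft modulus ratio."""
        if self.mode == "gradient":
            r = anisotropy_gradient(mesh, tri, self.bottom_ratio, self.top_ratio)
        else:
            r = np.full(len(tri.triangles),
                        1.0 if self.mode == "isotropic" else self.ratio)
        return r if subset is None else r[subset]
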