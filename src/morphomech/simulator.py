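"""Growth-loop simulation: equilibrate, grow where strained, repeat.

A Scenario binds a synthetic tissue template to region-wise mechanical
parameters: turgor pressure, outer-wall moduli and anisotropy, inner-wall
spring stiffness, extensibility and yield thresholds, plus optional timed
parameter changes.  The simulation alternates mechanical equilibration
(turgor held constant) with viscoplastic rest-shape updates wherever the
elastic strain exceeds its threshold, recording node positions, per-element
strain/stress norms, cell volumes and scalar shape metrics along the way.

No cell division is modeled; runs stop with a warning once the median cell
volume exceeds three times its initial value, where the fixed-topology
assumption stops being biologically sensible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth as gr
from .mechanics import (MembraneSet, PressureSet, SpringSet,
                        effective_pressures)
from .solver import MechanicalState, SolverConfig, solve_equilibrium
from .template_gen import (AnisotropyField, DomeSpec, RegionSpec,
                           assign_regions, build_dome)
from .tissue_mesh import TissueMesh, Triangulation, export_vtk, triangulate

__all__ = ["RegionParams", "Scenario", "ShapeMetrics", "Trajectory",
           "SimulationSystem", "build_system", "run_simulation",
           "compute_metrics", "residual_stress_experiment", "scenario_suite"]


@dataclass
class RegionParams:
    """Mechanical parameters of one region (arbitrary consistent units).

    modulus is the outer periclinal wall modulus along the soft material
    axis; the stiff axis carries modulus x anisotropy ratio and the shear
    modulus is sqrt(Ex Ey)/2 (isotropic-like, null Poisson coupling).
    inner_modulus is the inner-wall spring stiffness per unit rest length.
    """

    pressure: float = 1.0
    modulus: float = 8.0
    anisotropy: AnisotropyField = field(default_factory=AnisotropyField)
    extensibility: float = 0.2
    threshold: float = 0.02
    shear_threshold: float | None = None
    inner_modulus: float = 4.0
    inner_extensibility: float | None = None
    inner_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")
        if self.shear_threshold is None:
            self.shear_threshold = self.threshold
        if self.inner_extensibility is None:
            self.inner_extensibility = self.extensibility
        if self.inner_threshold is None:
            self.inner_threshold = self.threshold


@dataclass
class Scenario:
    """A named experiment: template, region labels, parameters, schedule."""

    name: str
    dome: DomeSpec = field(default_factory=DomeSpec)
    regions: list[RegionSpec] = field(default_factory=list)
    params: dict[str, RegionParams] = field(default_factory=dict)
    events: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    default_region: str = "Pe"
    dt: float = 1.0
    n_steps: int = 30
    growth_mode: str = "material"

    def region_params(self, label: str) -> RegionParams:
        if label in self.params:
            return self.params[label]
        if "default" in self.params:
            return self.params["default"]
        return RegionParams()


@dataclass
class ShapeMetrics:
    """Scalar readouts of the tissue shape (np.nan when undefined)."""

    height: float
    base_width: float
    aspect: float
    apical_width: float = np.nan     # width of the upper half of the dome
    bump_height: float = np.nan
    asymmetry_index: float = np.nan
    apex_deflection: float = np.nan
    total_volume: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


class SimulationSystem:
    """Assembled mechanical system plus growth parameters and bookkeeping."""

    def __init__(self, mesh: TissueMesh, scenario: Scenario):
        self.mesh = mesh
        self.scenario = scenario
        if scenario.regions:
            self.labels = assign_regions(mesh, scenario.regions,
                                         scenario.default_region)
        else:
            self.labels = {ci: scenario.default_region
                           for ci in range(len(mesh.cells))}

        tri = triangulate(mesh)
        self.tri_all = tri
        wl = mesh.wall_labels
        x0 = mesh.vertices
        # the base plane is a symmetry cut through inner tissue, not
        # epidermis: its walls get spring elements, not stiff membranes
        zmin = x0[:, 2].min()
        wall_base = np.array([np.all(x0[w][:, 2] < zmin + 1e-9)
                              for w in mesh.walls])
        outer = np.array([wl[w] == "outer-periclinal" and not wall_base[w]
                          for w in tri.tri_wall])
        self.outer_tri = np.flatnonzero(outer)

        # parent cell and region of every outer-wall triangle
        self.tri_cell = np.array([mesh.wall_cells[tri.tri_wall[t]][0]
                                  for t in self.outer_tri])
        self.tri_region = np.array([self.labels[c] for c in self.tri_cell])

        tris = tri.triangles[self.outer_tri]
        cents = x0[tris].mean(axis=1)
        e1 = x0[tris[:, 1]] - x0[tris[:, 0]]
        e2 = x0[tris[:, 2]] - x0[tris[:, 0]]
        normals = np.cross(e1, e2)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)

        nT = len(tris)
        self.tri_ratio = np.ones(nT)
        self.tri_modulus = np.empty(nT)
        dirs = np.empty((nT, 3))
        for region in np.unique(self.tri_region):
            rp = scenario.region_params(region)
            m = self.tri_region == region
            self.tri_modulus[m] = rp.modulus
            af = rp.anisotropy
            dirs[m] = af.directions(cents[m], normals[m])
            if af.mode == "gradient":
                self.tri_ratio[m] = af.ratios(mesh, tri)[self.outer_tri][m]
            elif af.mode != "isotropic":
                self.tri_ratio[m] = af.ratio

        Ey = self.tri_modulus
        Ex = self.tri_modulus * self.tri_ratio
        G = np.sqrt(Ex * Ey) / 2.0
        membranes = MembraneSet.from_triangles(x0, tris, dirs, Ex, Ey, G)

        # growth parameters per membrane triangle
        self.phi = np.empty(nT)
        self.thr_x = np.empty(nT)
        self.thr_y = np.empty(nT)
        self.thr_s = np.empty(nT)
        for region in np.unique(self.tri_region):
            rp = scenario.region_params(region)
            m = self.tri_region == region
            self.phi[m] = rp.extensibility
            self.thr_x[m] = rp.threshold
            self.thr_y[m] = rp.threshold
            self.thr_s[m] = rp.shear_threshold

        # springs: unique edges of the triangulated non-outer walls
        inner_tri = np.flatnonzero(~outer)
        edges: dict[tuple[int, int], list[int]] = {}
        for t in inner_tri:
            wi = tri.tri_wall[t]
            a, b, c = tri.triangles[t]
            for u, v in ((a, b), (b, c), (c, a)):
                key = (min(u, v), max(u, v))
                edges.setdefault(key, [])
                for ci in mesh.wall_cells[wi]:
                    if ci not in edges[key]:
                        edges[key].append(ci)
        pairs = np.array(sorted(edges), int).reshape(-1, 2)
        self.spring_cells = [tuple(edges[tuple(p)]) for p in map(tuple, pairs)]
        l0 = np.linalg.norm(x0[pairs[:, 1]] - x0[pairs[:, 0]], axis=1) \
            if len(pairs) else np.zeros(0)

        def inner_of(cells, attr):
            vals = [getattr(scenario.region_params(self.labels[c]), attr)
                    for c in cells]
            return float(np.mean(vals))

        kdens = np.array([inner_of(cs, "inner_modulus") for cs in self.spring_cells])
        self.spring_phi = np.array([inner_of(cs, "inner_extensibility")
                                    for cs in self.spring_cells])
        self.spring_thr = np.array([inner_of(cs, "inner_threshold")
                                    for cs in self.spring_cells])
        springs = SpringSet(pairs, kdens * l0 if len(pairs) else kdens, l0)

        # turgor loads on the full wall triangulation
        self.cell_pressures = np.array(
            [scenario.region_params(self.labels[c]).pressure
             for c in range(len(mesh.cells))])
        pressure = PressureSet(tri.triangles, self._tri_pressures())

        self.state = MechanicalState(x0.copy(), membranes, springs, pressure,
                                     list(mesh.boundary))

        # per-cell oriented triangle tables for fast volume evaluation
        vt, vc = [], []
        for ci, cell in enumerate(mesh.cells):
            for wi in cell:
                sgn = mesh.wall_orientation(ci, wi)
                sel = np.flatnonzero(tri.tri_wall == wi)
                t = tri.triangles[sel]
                vt.append(t if sgn > 0 else t[:, [0, 2, 1]])
                vc.append(np.full(len(sel), ci))
        self._vol_tris = np.concatenate(vt)
        self._vol_cell = np.concatenate(vc)

        self.positions0 = x0.copy()
        self.volumes0 = self.cell_volumes(x0)
        self.rest_area0 = membranes.rest_area.copy()

    # -- loads and events --------------------------------------------------

    def _tri_pressures(self) -> np.ndarray:
        per_wall = effective_pressures(self.mesh, self.cell_pressures)
        return per_wall[self.tri_all.tri_wall]

    def refresh_pressure(self) -> None:
        self.state.pressure.values = self._tri_pressures()

    def set_pressures(self, value: float) -> None:
        self.cell_pressures[:] = value
        self.refresh_pressure()

    def apply_event(self, changes: dict[str, dict[str, float]]) -> None:
        """Apply region-wise parameter changes (absolute values) between
        steps.  Region '*' addresses every region."""
        for region, fields_ in changes.items():
            cmask = np.array([region in ("*", self.labels[c])
                              for c in range(len(self.mesh.cells))])
            tmask = np.isin(self.tri_cell, np.flatnonzero(cmask))
            smask = np.array([any(cmask[c] for c in cs)
                              for cs in self.spring_cells]) \
                if self.spring_cells else np.zeros(0, bool)
            for key, val in fields_.items():
                if key == "pressure":
                    self.cell_pressures[cmask] = val
                    self.refresh_pressure()
                elif key == "modulus":
                    mem = self.state.membranes
                    self.tri_modulus[tmask] = val
                    mem.Ey[tmask] = val
                    mem.Ex[tmask] = val * self.tri_ratio[tmask]
                    mem.G[tmask] = np.sqrt(mem.Ex[tmask] * mem.Ey[tmask]) / 2
                elif key == "extensibility":
                    self.phi[tmask] = val
                elif key == "threshold":
                    self.thr_x[tmask] = self.thr_y[tmask] = val
                elif key == "shear_threshold":
                    self.thr_s[tmask] = val
                elif key == "inner_modulus":
                    sp = self.state.springs
                    sp.k[smask] = val * sp.l0[smask]
                elif key == "inner_extensibility":
                    self.spring_phi[smask] = val
                elif key == "inner_threshold":
                    self.spring_thr[smask] = val
                else:
                    raise ValueError(f"unknown event parameter {key!r}")

    # -- observables -------------------------------------------------------

    def cell_volumes(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.state.positions if x is None else x
        t = self._vol_tris
        vol6 = np.einsum("ij,ij->i", x[t[:, 0]], np.cross(x[t[:, 1]], x[t[:, 2]]))
        return np.bincount(self._vol_cell, vol6,
                           minlength=len(self.mesh.cells)) / 6.0

    def strain_stress_norms(self, x: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
        x = self.state.positions if x is None else x
        E = self.state.membranes.strains(x)
        S = self.state.membranes.stresses(E)
        return (np.linalg.norm(E, axis=(1, 2)), np.linalg.norm(S, axis=(1, 2)))

    def solver_config(self, **overrides) -> SolverConfig:
        """Default solver tolerances scaled to the model: residual below
        1e-6 x (max pressure x mean membrane rest area)."""
        pscale = float(self.cell_pressures.max()) or 1.0
        amean = float(self.state.membranes.rest_area.mean())
        defaults = dict(eta=100.0,
                        force_tol=1e-6 * pscale * amean,
                        max_iters=400, cg_tol=1e-5, cg_max_iters=300,
                        fd_probe=1e-6 * np.sqrt(amean))
        defaults.update(overrides)
        return SolverConfig(**defaults)

    def metrics(self, x: np.ndarray | None = None) -> ShapeMetrics:
        x = self.state.positions if x is None else x
        return compute_metrics(self.mesh, x, self.labels,
                               initial_positions=self.positions0, system=self)


def build_system(mesh: TissueMesh | None, scenario: Scenario) -> SimulationSystem:
    """Assemble the mechanical system for a scenario; builds the scenario's
    dome template when no mesh is passed."""
    if mesh is None:
        mesh = build_dome(scenario.dome)
    return SimulationSystem(mesh, scenario)


# -- shape metrics ----------------------------------------------------------

def _surface_nodes(mesh: TissueMesh, labels: dict[int, str],
                   region: str | None, exclude: frozenset | set = frozenset()
                   ) -> np.ndarray:
    """Nodes of outer-periclinal walls whose cell is in (or out of) a region,
    excluding the base plane."""
    wl = mesh.wall_labels
    keep: set[int] = set()
    for wi, adj in enumerate(mesh.wall_cells):
        if wl[wi] != "outer-periclinal":
            continue
        lab = labels.get(adj[0], "")
        if region is not None and lab != region:
            continue
        if region is None and lab in exclude:
            continue
        keep.update(int(v) for v in mesh.walls[wi])
    nodes = np.array(sorted(keep), int)
    if len(nodes):
        nodes = nodes[mesh.vertices[nodes, 2] > 1e-9]
    return nodes


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere through a point cloud."""
    A = np.column_stack([2 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r = float(np.sqrt(sol[3] + c @ c))
    return c, r


def compute_metrics(mesh: TissueMesh, positions: np.ndarray,
                    labels: dict[int, str],
                    initial_positions: np.ndarray | None = None,
                    system: "SimulationSystem | None" = None,
                    primordium: str = "Pr", adaxial: str = "Ad",
                    abaxial: str = "Ab") -> ShapeMetrics:
    """Scalar shape readouts; region-dependent metrics are NaN when the
    region is absent."""
    x = np.asarray(positions, float)
    height = float(x[:, 2].max())
    basal = np.abs(x[:, 2]) < 1e-9
    width = 2.0 * float(np.hypot(x[basal, 0], x[basal, 1]).max()) \
        if basal.any() else np.nan
    aspect = height / width if width else np.nan
    upper = x[:, 2] >= 0.5 * height
    apical = 2.0 * float(np.hypot(x[upper, 0], x[upper, 1]).max())

    bump = np.nan
    defl = np.nan
    pr_labels = {primordium, adaxial, abaxial}
    present = pr_labels & set(labels.values())
    pr_nodes = np.unique(np.concatenate(
        [_surface_nodes(mesh, labels, lab) for lab in present])) \
        if present else np.zeros(0, int)
    if len(pr_nodes):
        ref = _surface_nodes(mesh, labels, None, exclude=pr_labels)
        c, r = _fit_sphere(x[ref])
        prot = np.linalg.norm(x[pr_nodes] - c, axis=1) - r
        bump = max(0.0, float(prot.max()))
        # where does the organ develop?  angular offset of the
        # protrusion-weighted bulge center from the patch middle,
        # positive when the bulge sits on the apex (adaxial) side
        w = np.clip(prot, 0.0, None)
        if w.sum() > 0:
            def polar(p):
                return float(np.arccos(np.clip(p[2] / np.linalg.norm(p), -1, 1)))
            defl = polar(x[pr_nodes].mean(axis=0)) - \
                polar((w[:, None] * x[pr_nodes]).sum(axis=0) / w.sum())

    asym = np.nan
    if initial_positions is not None and len(pr_nodes):
        x0 = np.asarray(initial_positions, float)
        if system is not None:
            lam_ab = _meridional_stretch(system, x, x0, abaxial)
            lam_ad = _meridional_stretch(system, x, x0, adaxial)
            if lam_ab is not None and lam_ad is not None:
                asym = float(lam_ab / lam_ad)

    vol = np.nan
    if system is not None:
        vol = float(system.cell_volumes(x).sum())
    return ShapeMetrics(height, width, aspect, apical, bump, asym, defl, vol)


def _meridional_stretch(system: SimulationSystem, x: np.ndarray,
                        x0: np.ndarray, region: str) -> float | None:
    """Mean stretch of a region's outer-wall triangles along the initial
    meridional surface direction (abaxial-vs-adaxial expansion readout)."""
    sel = np.flatnonzero(system.tri_region == region)
    if not len(sel):
        return None
    tris = system.tri_all.triangles[system.outer_tri[sel]]
    lams = []
    zhat = np.array([0.0, 0.0, 1.0])
    for t in tris:
        D0 = np.stack([x0[t[1]] - x0[t[0]], x0[t[2]] - x0[t[0]]], axis=1)
        D1 = np.stack([x[t[1]] - x[t[0]], x[t[2]] - x[t[0]]], axis=1)
        n = np.cross(D0[:, 0], D0[:, 1])
        n /= np.linalg.norm(n)
        m = zhat - (zhat @ n) * n  # meridional tangent (uphill) at t=0
        nm = np.linalg.norm(m)
        if nm < 1e-8:
            continue
        m /= nm
        F = D1 @ np.linalg.pinv(D0)
        lams.append(np.linalg.norm(F @ m))
    return float(np.mean(lams)) if lams else None


# -- trajectory --------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    step: int
    time: float
    positions: np.ndarray
    strain_norm: np.ndarray
    stress_norm: np.ndarray
    cell_volumes: np.ndarray
    metrics: ShapeMetrics
    residual: float


@dataclass
class Trajectory:
    scenario: str
    dt: float
    records: list[TrajectoryRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({"step": r.step, "time": r.time, **r.metrics.as_dict(),
                         "max_strain": float(r.strain_norm.max(initial=0.0)),
                         "max_stress": float(r.stress_norm.max(initial=0.0)),
                         "residual": r.residual})
        return pd.DataFrame(rows)

    def save(self, outdir, system: SimulationSystem) -> None:
        """Write a VTK series, metrics.csv and a JSON run manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        region_names = sorted(set(system.labels.values()))
        rid = {n: i for i, n in enumerate(region_names)}
        tri = Triangulation(system.tri_all.triangles[system.outer_tri],
                            system.tri_all.tri_wall[system.outer_tri])
        region_id = np.array([rid[r] for r in system.tri_region], float)
        for r in self.records:
            export_vtk(system.mesh, r.positions, out / f"step_{r.step:05d}.vtk",
                       {"strain_norm": r.strain_norm,
                        "stress_norm": r.stress_norm,
                        "region_id": region_id},
                       triangulation=tri)
        self.metrics_frame().to_csv(out / "metrics.csv", index=False,
                                    float_format="%.10g")
        manifest = {"scenario": self.scenario, "dt": self.dt,
                    "steps_recorded": [r.step for r in self.records],
                    "regions": region_names,
                    **{k: v for k, v in self.meta.items() if k != "system"}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


# -- the growth loop ---------------------------------------------------------

def run_simulation(mesh: TissueMesh | None, scenario: Scenario,
                   solver_config: SolverConfig | None = None,
                   record_stride: int = 5,
                   system: SimulationSystem | None = None) -> Trajectory:
    """Run the quasi-static growth loop for scenario.n_steps steps.

    Each step: (1) the tissue is at mechanical equilibrium under constant
    turgor; (2) elements whose elastic strain exceeds the yield threshold
    grow (rest shapes extend); (3) the tissue re-equilibrates.  Scheduled
    events apply between steps, never during an equilibration.  Raises on
    solver failure; warns (and stops early) once cell volumes exceed 3x
    their initial values, the regime the fixed topology is meant for.
    """
    sys_ = system if system is not None else build_system(mesh, scenario)
    cfg = solver_config if solver_config is not None else sys_.solver_config()
    dt = scenario.dt

    res = solve_equilibrium(sys_.state, cfg)
    if not res.converged:
        raise RuntimeError(f"initial equilibration failed at residual "
                           f"{res.residual:.3g}")
    traj = Trajectory(scenario.name, dt,
                      meta={"n_steps": scenario.n_steps,
                            "n_cells": len(sys_.mesh.cells),
                            "n_membranes": len(sys_.state.membranes),
                            "n_springs": len(sys_.state.springs),
                            "system": sys_})

    def record(step):
        sn, tn = sys_.strain_stress_norms()
        traj.records.append(TrajectoryRecord(
            step, step * dt, sys_.state.positions.copy(), sn, tn,
            sys_.cell_volumes(), sys_.metrics(), res.residual))

    record(0)
    warned = False
    for step in range(1, scenario.n_steps + 1):
        if step in scenario.events:
            sys_.apply_event(scenario.events[step])
        x = sys_.state.positions
        E = sys_.state.membranes.strains(x)
        gr.grow_membranes(sys_.state.membranes, E, sys_.phi, sys_.thr_x,
                          sys_.thr_y, sys_.thr_s, dt, scenario.growth_mode)
        gr.grow_springs(sys_.state.springs, x, sys_.spring_phi,
                        sys_.spring_thr, dt)
        res = solve_equilibrium(sys_.state, cfg)
        if not res.converged:
            raise RuntimeError(f"equilibration failed at step {step} "
                               f"(residual {res.residual:.3g})")
        vols = sys_.cell_volumes()
        ratio = vols / sys_.volumes0
        if not warned and ratio.max() > 3.0:
            warnings.warn(f"step {step}: a cell exceeded 3x its initial "
                          "volume (no cell division is modeled)", stacklevel=2)
            warned = True
        if step % record_stride == 0 or step == scenario.n_steps:
            record(step)
        if np.median(ratio) > 3.0:
            warnings.warn(f"stopping at step {step}: median cell volume "
                          "exceeded 3x initial", stacklevel=2)
            break
        if ratio.min() <= 0.0:
            warnings.warn(f"stopping at step {step}: a cell collapsed to "
                          "non-positive volume", stacklevel=2)
            break
    return traj


def residual_stress_experiment(system: SimulationSystem,
                               solver_config: SolverConfig | None = None
                               ) -> dict:
    """Remove all turgor from a (grown) state and re-equilibrate.

    Nonzero remaining element stress reveals geometric incompatibility of
    the grown rest configurations.  Returns the relaxed positions and the
    per-element stress measures at zero load.
    """
    cfg = solver_config if solver_config is not None else system.solver_config()
    system.set_pressures(0.0)
    res = solve_equilibrium(system.state, cfg)
    sn, tn = system.strain_stress_norms()
    spring_force = np.abs(system.state.springs.k
                          * system.state.springs.strains(system.state.positions)) \
        if len(system.state.springs) else np.zeros(0)
    return {"positions": system.state.positions.copy(),
            "strain_norm": sn, "stress_norm": tn,
            "spring_force": spring_force,
            "max_stress": float(tn.max(initial=0.0)),
            "residual": res.residual, "converged": res.converged}


def scenario_suite() -> dict[str, Scenario]:
    """Named presets for the organogenesis experiments (see scenarios)."""
    from .scenarios import scenario_suite as suite
    return suite()
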