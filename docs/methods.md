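# Methods

This note documents the model, the numerical choices, the synthetic
templates and the design decisions behind `morphomech`, in the order a
reader would meet them.

## Mechanical model

**Tissue representation.** A tissue is a shared-vertex cellular complex:
vertices at wall junctions, polygonal walls, polyhedral cells. Walls are
fan-triangulated from their lowest-index vertex — deterministic and
adequate for the near-convex, mildly warped wall polygons the generator
produces; each flat triangle carries its own area and normal, so
non-planar walls need no special treatment. Outer walls wind outward;
inner walls wind out of their lower-index cell. That orientation
convention is part of the tissue-JSON schema and everything (volumes,
validation, wall pressures) relies on it.

**Elasticity.** Outer (periclinal) walls carry orthotropic St-Venant
membrane triangles. Each element stores a 2×2 rest edge matrix R in its
material frame (stiff axis x from the anisotropy field, y orthogonal in
the rest plane); the elastic map is the 3×2 gradient F = D R⁻¹ with D the
current edge vectors, strain is E = (FᵀF − I)/2, and the energy per rest
area is W = ½(E_x E_xx² + E_y E_yy² + G(2E_xy)²). Moduli are
thickness-integrated (force/length): wall thickness never appears
separately. Poisson coupling is zero and bending stiffness is absent —
out-of-plane resistance comes from tension only. The shear modulus
defaults to √(E_x E_y)/2, the no-Poisson isotropic value extended
symmetrically to the orthotropic case. Nodal forces are the exact
analytic gradient of the element energy (midpoint quadrature, energy
uniform per triangle); the test suite verifies them against central
finite differences everywhere, which is the module's master check.

Inner walls carry 1D springs on the edges of their triangulation
(polygon edges plus fan diagonals — the diagonals brace the otherwise
floppy quadrilateral walls). Spring force is k(l − l₀)/l₀: strain-based,
so k keeps force units and growth of l₀ does not soften the element.
Spring stiffness is assembled as k = ρ·l₀ with ρ a per-region stiffness
density, making the network's strain response roughly mesh-independent.

**Turgor.** Pressure is converted to nodal loads as P A n/3 per triangle
node, with current area and normal. Every wall is pressure-bearing; an
inner wall carries the signed difference of its two cells' pressures, so
uniform turgor loads only the tissue boundary, while a locally
pressurized cell group pushes on its neighbors through otherwise massless
inner faces. For closed cells these nodal loads are exactly the gradient
of −Σ_c P_c V_c, which gives the solver a true potential
Π = W_elastic + U_springs − Σ P V to descend.

**Basal boundary.** Basal nodes slide freely in the base plane (normal
displacement projected out; reaction forces carry the net vertical turgor
load). Base-plane walls are treated as inner-type spring walls, not
epidermis: the base is a symmetry cut through the tissue, and giving it
stiff sub-threshold membranes pins the dome footprint and spuriously
breaks self-similar growth of the homogeneous dome.

## Growth law

Growth is thresholded viscoplastic creep of the rest configuration:

    L = Φ · ramp(E − E_y),    R ← (I + Δt L) R,
    l₀ ← l₀ (1 + Δt Φ max(ε − ε_y, 0))     (springs)

The ramp acts componentwise in the orthotropic material frame: normal
components max(E_ii − threshold, 0), tension only; the shear component
keeps its sign with its own threshold (default equal to the normal one).
This keeps plastic flow aligned with the anisotropy structure of the
stiffness tensor; a principal-strain-frame variant is available behind
`growth_mode="principal"` for sensitivity checks. One known corner: a
pure shear excess shrinks rest area at second order, O((Δt L_xy)²), so
strict area monotonicity holds in the law's physical scope
(tension-dominated states) rather than for arbitrary strain input.

The incremental update is first-order; the simulation loop enforces
Δt‖L‖ ≤ 0.5 hard (error) and is sized so that typical per-step growth is
~1–3%. Convergence to the matrix-exponential limit at rate O(Δt) is
verified in the tests. Elements at or below threshold are never touched:
a fully sub-threshold simulation leaves every rest shape bit-identical,
and a 100-step neutrality run asserts exactly that.

In 1D the law reduces to a Maxwell element with a frictional threshold:
a spring under constant load locks its elastic strain at ε = f/k and the
rest length creeps at Φ(ε − ε_y). The simulated steady creep rate matches
this closed form to 0.1% at fine steps and to 1% at the production step
size; a sub-threshold load creeps exactly zero.

## Equilibrium solver

Between growth increments the tissue is assumed mechanically equilibrated
(elastic response much faster than growth). The solver minimizes Π by
implicit steps: solve (I − ηK)Δx = ηf with CG, where K = ∂f/∂x is applied
matrix-free as a central finite difference of the force vector (probe
~1e-6 of the geometry scale). Large η makes the step Newton-like; η is
halved when CG fails, the potential rises, or a triangle's area collapses
below 1e-8 of its rest area, and regrown after successful steps.
Constraints are enforced by projecting forces, probe directions and
updates, so constrained coordinates are exact at every iterate.
Convergence is declared at a max-norm force residual below
1e-6 × (max pressure × mean membrane rest area) — a scale-aware default;
everything is configurable through `SolverConfig` / the YAML solver
block. The solver has no random component: identical inputs give
bit-identical trajectories.

The implicit solution is cross-checked against an independent damped
explicit relaxation on a pressurized icosphere (agreement to 1e-4 of the
radius) and against analytic spring Hessians.

## Synthetic templates

`build_dome` constructs the standard template: a hemispherical dome of
polyhedral cells on a flat base — a spherical lattice with `resolution`
azimuthal sectors, resolution/4 + 1 polar bands, and `layers` radial
shells over a single core cell. The apex band is half-width so apex
facets stay comparable in size to the ring facets; with uniform bands the
oversized apex cap concentrated elastic strain (a discretization
artifact, confirmed by polar refinement) and biased growth axially even
for homogeneous tissue. The default template (radius 1, 3 shells,
resolution 18) has 220 cells, in the few-hundred-cell regime the
simulations are designed for. Optional seeded vertex jitter breaks the
rotational symmetry; it is off by default so all presets are exactly
reproducible.

Regions (central zone, periphery, primordium Pr, frontier Fr,
adaxial/abaxial Ad/Ab) are assigned by geometric predicates — height
bands, spherical caps, rings, cap halves — applied in priority order,
optionally restricted to radial shells (e.g. an inner cell group).
Anisotropy direction fields give each membrane triangle its stiff axis:
circumferential about the dome axis, ortho-radial about a primordium
center, or graded in height.

What the generator does *not* emulate: real meristems have irregular cell
shapes and sizes, curved walls, cell division, and wall-property noise.
Passing the scenario tests therefore shows that the mechanical framework
produces the right shape responses to region-wise parameter changes on an
idealized geometry — not that it quantitatively predicts any particular
specimen.

## Study conditions (baseline parameters)

All quantities are in consistent model units (dome radius 1, turgor 1).

| parameter | default | rationale |
|---|---|---|
| turgor P | 1 | sets the force scale |
| epidermal modulus (soft axis) | 4 | membrane tension ≈ P·R/2 = 0.5 → epidermal strain a few % above threshold |
| inner spring stiffness density ρ | 1 | L1 is the main load-bearing layer (4× softer interior); keeps homogeneous growth self-similar while still containing a 3× inner-pressure load |
| anisotropy ratio (stiff/soft) | 4–6 | strong but not rigid microtubule-like anisotropy |
| yield threshold E_y | 0.02 | growth regime: elastic strains ~2–3× threshold |
| extensibility Φ | 0.2 /time | ~1–3% volume growth per step at Δt = 1 |
| Δt | 1 | keeps Δt‖L‖ ≲ 0.01, far inside the incremental bound |

Scenario presets change exactly one thing against this baseline
(anisotropy extent, a region's modulus, inner pressure, frontier
properties, Ad/Ab contrast), so comparisons at matched step counts isolate
that parameter. The inner-pressure scenario (3× turgor in a buried cell
group) is physically violent: the group creeps fast and the comparison is
made at 8 steps, inside the window where no cell has exceeded 3× its
initial volume — the same volume bound at which any simulation stops with
a warning, since cell division is not modeled. The run loop also stops if
a cell collapses to non-positive volume.

## Shape metrics

`compute_metrics` reports: dome height (apex over base plane); base and
apical widths (largest horizontal extent of basal nodes / of the upper
half); aspect ratio; bump height (max outward deviation of the
primordium-patch surface from a least-squares sphere fitted to the
non-patch surface); apex deflection (angular offset of the
protrusion-weighted bulge center from the plain patch centroid, positive
toward the apex — this isolates where the organ develops from the global
dome growth, which dominates naive centroid or farthest-node readouts);
and the asymmetry index (mean meridional surface stretch of the abaxial
region over the adaxial one, measured per-triangle against the initial
configuration). Missing regions yield NaN, not errors.

## Residual stress experiment

After heterogeneous growth, setting all pressures to zero and
re-equilibrating leaves elements stressed: grown rest shapes are
geometrically incompatible. The compatible control scales every rest
shape by one factor, equilibrates under turgor, then unloads — and
relaxes to solver noise (~1e-7), six orders below the heterogeneous
residual (~0.13). Protocol matters: unloading from a state far from the
compatible manifold can strand the bending-free membrane model in a
shallow self-stressed local minimum (~0.2% of the loaded stress) on
coarse meshes, because flat St-Venant triangles resist in-plane
compression instead of wrinkling. This is a known limitation of
membrane-only elements, not of the growth law.

## Known limitations

- No cell division; runs are meaningful only while cell volumes stay
  within ~3× of initial (enforced by the stop guard).
- No bending stiffness: compressed membranes carry unphysical in-plane
  compression rather than wrinkling; shapes dominated by flexure are out
  of scope.
- Constant pressure, no water transport: crushed cells lose volume
  without osmotic pushback, which is why the 3× inner-pressure scenario
  eventually inverts cells if run past its validity window.
- No stress→anisotropy feedback: direction fields are prescribed per
  scenario, not emergent.
- Linear wall material; no strain-stiffening.
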