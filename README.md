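# morphomech

Turgor-driven 3D biomechanical simulation of plant tissue morphogenesis.

Plant cells are pressurized boxes: the protoplast pushes on a stiff
polysaccharide wall, the wall stretches elastically, and — once the stretch
passes a yield point — yields irreversibly, which is what growth *is* at the
tissue scale. `morphomech` simulates this on multicellular 3D tissues: a
shoot-apical-meristem-like dome of a few hundred polyhedral cells whose
walls deform under turgor and creep viscoplastically, reproducing the core
organogenesis behaviors — axial (stem-like) growth under circumferential
wall anisotropy, primordium outgrowth by local wall softening, the role of
a stiff organ boundary, and the adaxial/abaxial asymmetry of a young
flower bud. It is aimed at computational biologists who want a compact,
fully scriptable mechanical meristem to test growth-regulation hypotheses.

## Model

Each wall element stores its own stress-free *grown* configuration,
following the multiplicative split F = F_e F_g of deformation into an
elastic part and an irreversible growth part. Outer (periclinal) walls are
thickness-integrated orthotropic membranes: with Green–Lagrange strain
E = (F_eᵀF_e − I)/2 evaluated in the material frame (stiff axis x set by a
cortical-microtubule-like direction field), the second Piola–Kirchhoff
stress is S = C : E with diagonal Voigt stiffness C = diag(E_x, E_y, G)
(null Poisson coupling). Inner walls are 1D elasto-plastic springs with
force k(l − l₀)/l₀. Turgor P loads every wall face with P A n/3 per node
(net wall pressure = difference between its two cells, so uniform turgor
loads only the tissue surface).

Growth is a tensorial Lockhart law on strain: the growth-rate tensor

    L = Φ · ⟨E − E_y⟩₊

is the thresholded strain excess (componentwise ramp in the material
frame, tension only) scaled by the wall extensibility Φ, and the rest
shape updates incrementally, R ← (I + Δt L) R. Below threshold the
response is purely elastic; above it the wall creeps at a rate
proportional to the excess strain — Lockhart's relation, generalized to
anisotropic membranes. Grown rest shapes of neighboring elements need not
stay geometrically compatible, so removing the turgor after heterogeneous
growth leaves residual stress.

Because wall mechanics equilibrate much faster than growth, the loop is
quasi-static: equilibrate (implicit matrix-free Newton-like steps with
conjugate-gradient solves, constraints enforced by projection) → grow
where strain exceeds threshold → re-equilibrate.

## Worked example

Soften the outer walls of a small patch on the dome flank (3.3-fold) and
grow for 8 steps:

```python
from morphomech.scenarios import scenario_suite
from morphomech.simulator import run_simulation

scenario = scenario_suite(n_steps=8)["primordium"]
trajectory = run_simulation(None, scenario, record_stride=4)
for rec in trajectory.records:
    m = rec.metrics
    print(f"step {rec.step:2d}  height {m.height:.3f}  width {m.base_width:.3f}  "
          f"aspect {m.aspect:.3f}  bump {m.bump_height:.4f}")
```

prints

```
step  0  height 1.077  width 2.103  aspect 0.512  bump 0.0329
step  4  height 1.116  width 2.170  aspect 0.514  bump 0.0544
step  8  height 1.155  width 2.243  aspect 0.515  bump 0.0752
```

The dome (radius 1, 220 cells) inflates elastically at step 0 (the soft
patch already bulges 0.033), then grows: the whole tissue expands nearly
self-similarly (aspect ratio stays ≈ 0.51) while the softened patch
bulges out more than twice as far as the elastic bulge — a primordium
emerging by cell-autonomous wall loosening. `bump` is the maximal outward
deviation of the patch surface from a sphere fitted to the rest of the
dome, in units of the dome radius.

The same thing from the shell:

```bash
morphomech simulate --scenario primordium --steps 8 --stride 4 --out runs/pr
morphomech metrics --traj runs/pr
```

writes a VTK series (per-triangle strain/stress norms and region ids, for
ParaView-style inspection) plus `metrics.csv` and a JSON manifest. Other
subcommands: `generate` (dome templates as tissue-JSON), `export`
(tissue-JSON → VTK), `residual-stress` (grow, unload, report locked-in
stress). The preset names are the keys of
`morphomech.scenarios.scenario_suite()` and are printed when an unknown
scenario is requested.

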