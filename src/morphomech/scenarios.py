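"""Scripted organogenesis scenarios on the synthetic dome.

Every preset shares one template (a ~170-cell, 3-shell hemispherical dome)
and one baseline parameter set, and changes exactly one thing - anisotropy
extent, a region's rigidity, inner pressure, frontier properties - so that
runs are comparable at matched step counts.  Baseline values are in model
units (pressure 1, dome radius 1): epidermal modulus 4 with much softer
inner walls (spring stiffness density 1.0) makes the L1 the main
load-bearing layer and puts its turgor-driven membrane strain a few
percent above the 2% yield threshold, the regime where thresholded creep
growth operates.

Presets:
  uniform-dome          homogeneous isotropic growth
  aniso-dome-50         circumferential anisotropy on the lower half
  aniso-dome-80/40      anisotropy up to 80% / 40% of dome height
  gradient-dome         anisotropy graded from base to apex
  primordium            epidermal softening of a flank patch
  inner-soft            10-fold softening of inner cells under the patch
  inner-pressure        3-fold turgor increase in those inner cells
  primordium-frontier   softened patch ringed by stiffened frontier
  primordium-ortho      frontier stiff in the ortho-radial direction only
  primordium-extensible milder softening + raised extensibility
  flower-bud            soft primordium + ortho-radial frontier (symmetric)
  flower-stiff-adaxial  ... with a stiffened adaxial half
  flower-stiff-abaxial  ... with a stiffened abaxial half
  flower-aniso-abaxial  stiff and circumferentially anisotropic abaxial half
  flower-soft-abaxial   softened abaxial half
"""

from __future__ import annotations

import numpy as np

from .simulator import RegionParams, Scenario
from .template_gen import AnisotropyField, DomeSpec, RegionSpec

__all__ = ["scenario_suite", "baseline_params", "PRIMORDIUM_CENTER"]

#: flank direction of the incipient primordium (polar angle 45 deg)
PRIMORDIUM_CENTER = np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)])
_CAP = 0.42          # primordium cap half-angle (rad, ~24 deg)
_RING = 0.70         # frontier ring outer angle (rad, ~40 deg)


def baseline_params(**overrides) -> RegionParams:
    """The shared baseline: every scenario derives its regions from this."""
    base = dict(pressure=1.0, modulus=4.0, extensibility=0.2,
                threshold=0.02, inner_modulus=1.0)
    base.update(overrides)
    return RegionParams(**base)


def _dome(jitter=0.0, seed=None) -> DomeSpec:
    return DomeSpec(radius=1.0, layers=3, resolution=18,
                    jitter=jitter, seed=seed)


def _pr_cap(name="Pr", side=None) -> RegionSpec:
    return RegionSpec(name, "cap", center=PRIMORDIUM_CENTER, angle=_CAP,
                      side=side)


def _fr_ring() -> RegionSpec:
    return RegionSpec("Fr", "ring", center=PRIMORDIUM_CENTER,
                      inner_angle=_CAP, angle=_RING)


def scenario_suite(n_steps: int = 30, dome: DomeSpec | None = None
                   ) -> dict[str, Scenario]:
    """Build the named scenario presets (fresh Scenario objects each call)."""
    dome = dome or _dome()
    circ = AnisotropyField("circumferential", ratio=5.0)
    ortho = AnisotropyField("ortho-radial", center=PRIMORDIUM_CENTER, ratio=5.0)

    def sc(name, regions=(), params=None, **kw):
        p = {"default": baseline_params()}
        p.update(params or {})
        kw.setdefault("n_steps", n_steps)
        return Scenario(name, dome=dome, regions=list(regions), params=p, **kw)

    suite = {
        "uniform-dome": sc("uniform-dome"),
        "aniso-dome-50": sc(
            "aniso-dome-50",
            [RegionSpec("aniso", "height_band", 0.0, 0.5)],
            {"aniso": baseline_params(anisotropy=circ)}),
        "aniso-dome-80": sc(
            "aniso-dome-80",
            [RegionSpec("aniso", "height_band", 0.0, 0.8)],
            {"aniso": baseline_params(anisotropy=circ)}),
        "aniso-dome-40": sc(
            "aniso-dome-40",
            [RegionSpec("aniso", "height_band", 0.0, 0.4)],
            {"aniso": baseline_params(anisotropy=circ)}),
        "gradient-dome": sc(
            "gradient-dome",
            [RegionSpec("all", "all")],
            {"all": baseline_params(anisotropy=AnisotropyField(
                "gradient", bottom_ratio=5.0, top_ratio=1.0))}),
        "primordium": sc(
            "primordium", [_pr_cap()],
            {"Pr": baseline_params(modulus=1.2)}),
        # the surface patch above the inner group keeps baseline mechanics
        # but is labeled Pr so the bump-height readout tracks the same spot
        "inner-soft": sc(
            "inner-soft",
            [RegionSpec("Pr", "cap", center=PRIMORDIUM_CENTER, angle=_CAP,
                        layers=(3,)),
             RegionSpec("Pi", "cap", center=PRIMORDIUM_CENTER, angle=_CAP,
                        layers=(1, 2))],
            {"Pi": baseline_params(inner_modulus=0.1)}),
        "inner-pressure": sc(
            "inner-pressure",
            [RegionSpec("Pr", "cap", center=PRIMORDIUM_CENTER, angle=_CAP,
                        layers=(3,)),
             RegionSpec("Pi", "cap", center=PRIMORDIUM_CENTER, angle=_CAP,
                        layers=(1, 2))],
            {"Pi": baseline_params(pressure=3.0)}),
        "primordium-frontier": sc(
            "primordium-frontier", [_pr_cap(), _fr_ring()],
            {"Pr": baseline_params(modulus=1.2),
             "Fr": baseline_params(modulus=12.0)}),
        "primordium-ortho": sc(
            "primordium-ortho", [_pr_cap(), _fr_ring()],
            {"Pr": baseline_params(modulus=1.2),
             "Fr": baseline_params(anisotropy=ortho)}),
        "primordium-extensible": sc(
            "primordium-extensible", [_pr_cap(), _fr_ring()],
            {"Pr": baseline_params(modulus=2.4, extensibility=0.6),
             "Fr": baseline_params(modulus=12.0)}),
    }

    def flower(name, ad, ab):
        return sc(name,
                  [_pr_cap("Ab", side="abaxial"), _pr_cap("Ad", side="adaxial"),
                   _fr_ring()],
                  {"Ad": ad, "Ab": ab, "Fr": baseline_params(anisotropy=ortho)})

    soft = dict(modulus=2.0)
    # abaxial wall rigidity raised in the circumferential (ortho-radial)
    # direction only, leaving the meridional direction soft: expansion is
    # channeled along the meridian
    ab_aniso = AnisotropyField("ortho-radial", center=PRIMORDIUM_CENTER,
                               ratio=6.0)
    suite.update({
        "flower-bud": flower("flower-bud", baseline_params(**soft),
                             baseline_params(**soft)),
        "flower-stiff-adaxial": flower("flower-stiff-adaxial",
                                       baseline_params(modulus=5.0),
                                       baseline_params(**soft)),
        "flower-stiff-abaxial": flower("flower-stiff-abaxial",
                                       baseline_params(**soft),
                                       baseline_params(modulus=5.0)),
        "flower-aniso-abaxial": flower("flower-aniso-abaxial",
                                       baseline_params(**soft),
                                       baseline_params(modulus=1.5,
                                                       anisotropy=ab_aniso)),
        "flower-soft-abaxial": flower("flower-soft-abaxial",
                                      baseline_params(**soft),
                                      baseline_params(modulus=1.0)),
    })
    return suite
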