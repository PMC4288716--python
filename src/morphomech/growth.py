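"""Viscoplastic rest-shape evolution: the tensorial Lockhart growth law.

Growth is irreversible creep of the cell wall: whenever the elastic strain
of an element exceeds its yield threshold, the element's rest ("grown")
configuration extends at a rate proportional to the excess strain, scaled
by the wall extensibility Phi (units 1/time).  This is Lockhart's relation
- growth rate proportional to turgor-induced stretch above a yield point -
written on the Green-Lagrange strain tensor in the element's material
frame:

    L = Phi * ramp(E - E_y)      (ramp: tension-only, componentwise)
    R  <-  (I + dt L) R          (first-order incremental update)

The ramp acts componentwise in the orthotropic material frame (normal x,
normal y, shear), keeping plastic flow aligned with the anisotropy
structure of the stiffness; a principal-strain-frame variant is available
for sensitivity checks.  Compressive strains never trigger growth, so rest
lengths and areas only ever increase: grown shapes of neighboring elements
need not stay geometrically compatible, which is what leaves residual
stress after the load is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthParams", "GrowthIncrement", "ramp", "growth_rate",
           "update_rest_shape", "spring_growth", "grow_membranes",
           "grow_springs", "StepSizeError"]

#: hard cap on per-step growth ||L|| dt; above this the first-order
#: incremental update is invalid
MAX_STEP_GROWTH = 0.5
#: recommended accuracy bound checked by the simulation loop
SAFE_STEP_GROWTH = 0.1


class StepSizeError(ValueError):
    """Raised when dt * ||L|| violates the incremental-update assumption."""


@dataclass
class GrowthParams:
    """Extensibility and yield thresholds of one element class.

    phi : wall extensibility (1/time); 0 disables growth.
    threshold_x, threshold_y : yield strains of the two normal components in
        the material frame (dimensionless Green-Lagrange strain).
    shear_threshold : yield strain of the shear component (defaults to the
        normal threshold).
    mode : 'material' applies the ramp componentwise in the material frame;
        'principal' applies it to principal strains.
    """

    phi: float
    threshold_x: float
    threshold_y: float | None = None
    shear_threshold: float | None = None
    mode: str = "material"

    def __post_init__(self) -> None:
        if self.threshold_y is None:
            self.threshold_y = self.threshold_x
        if self.shear_threshold is None:
            self.shear_threshold = self.threshold_x
        if self.phi < 0 or min(self.threshold_x, self.threshold_y,
                               self.shear_threshold) < 0:
            raise ValueError("extensibility and thresholds must be >= 0")
        if self.mode not in ("material", "principal"):
            raise ValueError(f"unknown ramp mode {self.mode!r}")


@dataclass
class GrowthIncrement:
    """A growth-rate tensor and the time step over which it applies."""

    L: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, float).reshape(2, 2)
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def ramp(E: np.ndarray, threshold_x: float, threshold_y: float | None = None,
         shear_threshold: float | None = None, mode: str = "material") -> np.ndarray:
    """Thresholded strain excess (matrix ramp of E - E_y), batched or single.

    Normal components: max(component - threshold, 0) - tension only, so
    compressive strain never contributes.  The shear component keeps its
    sign: sign(Exy) * max(|Exy| - shear_threshold, 0).  In 'principal' mode
    the ramp is applied to the eigenvalues instead and rotated back.
    """
    if threshold_y is None:
        threshold_y = threshold_x
    if shear_threshold is None:
        shear_threshold = threshold_x
    E = np.asarray(E, float)
    single = E.ndim == 2
    Eb = E[None] if single else E
    out = np.zeros_like(Eb)
    if mode == "material":
        out[:, 0, 0] = np.maximum(Eb[:, 0, 0] - threshold_x, 0.0)
        out[:, 1, 1] = np.maximum(Eb[:, 1, 1] - threshold_y, 0.0)
        sh = 0.5 * (Eb[:, 0, 1] + Eb[:, 1, 0])
        out[:, 0, 1] = out[:, 1, 0] = np.sign(sh) * np.maximum(
            np.abs(sh) - shear_threshold, 0.0)
    elif mode == "principal":
        sym = 0.5 * (Eb + np.swapaxes(Eb, 1, 2))
        w, v = np.linalg.eigh(sym)
        w = np.maximum(w - threshold_x, 0.0)
        out = np.einsum("tij,tj,tkj->tik", v, w, v)
    else:
        raise ValueError(f"unknown ramp mode {mode!r}")
    return out[0] if single else out


def growth_rate(E: np.ndarray, params: GrowthParams) -> np.ndarray:
    """Growth-rate tensor L = Phi * ramp(E, E_y): zero at or below the
    threshold, linear in the excess strain and in Phi above it."""
    return params.phi * ramp(E, params.threshold_x, params.threshold_y,
                             params.shear_threshold, params.mode)


def update_rest_shape(R: np.ndarray, L: np.ndarray, dt: float) -> np.ndarray:
    """Incremental multiplicative growth update R <- (I + dt L) R.

    Forward-Euler discretization of Rdot = L R; accurate to first order in
    dt, hence the step-size guard dt ||L|| <= 0.5 (hard) with the loop
    aiming for <= 0.1.  With L identically zero the input is returned
    unchanged (bit-exact)."""
    R = np.asarray(R, float)
    L = np.asarray(L, float)
    if not np.any(L):
        return R
    norm = np.linalg.norm(L, 2) if L.ndim == 2 else \
        np.abs(np.linalg.eigvalsh(0.5 * (L + np.swapaxes(L, 1, 2)))).max()
    if dt * norm > MAX_STEP_GROWTH:
        raise StepSizeError(
            f"growth per step dt*||L|| = {dt * norm:.3g} exceeds "
            f"{MAX_STEP_GROWTH}; reduce dt")
    eye = np.eye(2) if L.ndim == 2 else np.eye(2)[None]
    return (eye + dt * L) @ R


def spring_growth(l0: np.ndarray, length: np.ndarray, phi, threshold,
                  dt: float) -> np.ndarray:
    """1D growth law for inner-wall springs.

    With strain eps = (l - l0)/l0, the rest length creeps as
    l0 <- l0 (1 + dt Phi max(eps - eps_y, 0)): unchanged at or below the
    yield strain, relative growth rate Phi*(eps - eps_y) above it.
    """
    l0 = np.asarray(l0, float)
    eps = (np.asarray(length, float) - l0) / l0
    excess = np.maximum(eps - threshold, 0.0)
    rate = np.asarray(phi * excess, float)
    if np.any(rate * dt > MAX_STEP_GROWTH):
        raise StepSizeError("spring growth per step exceeds the incremental bound")
    if not np.any(rate):
        return l0
    return l0 * (1.0 + dt * rate)


# -- batched element-set updates (used by the simulation loop) --------------

def grow_membranes(membranes, E: np.ndarray, phi: np.ndarray,
                   thr_x: np.ndarray, thr_y: np.ndarray, thr_s: np.ndarray,
                   dt: float, mode: str = "material") -> np.ndarray:
    """Apply one growth step to a MembraneSet in place.

    Only elements whose growth rate is nonzero are touched, so a fully
    sub-threshold step leaves every rest matrix bit-identical.  Returns the
    (T,2,2) growth-rate tensors actually applied.
    """
    T = len(membranes)
    L = np.zeros((T, 2, 2))
    if mode == "material":
        L[:, 0, 0] = np.maximum(E[:, 0, 0] - thr_x, 0.0)
        L[:, 1, 1] = np.maximum(E[:, 1, 1] - thr_y, 0.0)
        sh = 0.5 * (E[:, 0, 1] + E[:, 1, 0])
        L[:, 0, 1] = L[:, 1, 0] = np.sign(sh) * np.maximum(np.abs(sh) - thr_s, 0.0)
    else:
        sym = 0.5 * (E + np.swapaxes(E, 1, 2))
        w, v = np.linalg.eigh(sym)
        w = np.maximum(w - np.broadcast_to(np.asarray(thr_x, float),
                                           w.T.shape).T, 0.0)
        L = np.einsum("tij,tj,tkj->tik", v, w, v)
    L *= np.asarray(phi, float).reshape(-1, 1, 1) if np.ndim(phi) else phi
    active = np.flatnonzero(np.abs(L).sum(axis=(1, 2)) > 0.0)
    if len(active):
        norms = np.abs(np.linalg.eigvalsh(L[active])).max()
        if dt * norms > MAX_STEP_GROWTH:
            raise StepSizeError(
                f"growth per step dt*||L|| = {dt * norms:.3g} exceeds "
                f"{MAX_STEP_GROWTH}; reduce dt")
        R = membranes.R.copy()
        eye = np.eye(2)[None]
        R[active] = (eye + dt * L[active]) @ R[active]
        membranes.set_rest(R)
    return L


def grow_springs(springs, x: np.ndarray, phi: np.ndarray, threshold: np.ndarray,
                 dt: float) -> np.ndarray:
    """Apply one growth step to a SpringSet in place; returns the relative
    growth rates.  Untouched springs keep bit-identical rest lengths."""
    if not len(springs):
        return np.zeros(0)
    eps = springs.strains(x)
    rate = np.asarray(phi, float) * np.maximum(eps - np.asarray(threshold, float), 0.0)
    if np.any(rate * dt > MAX_STEP_GROWTH):
        raise StepSizeError("spring growth per step exceeds the incremental bound")
    active = np.flatnonzero(rate > 0.0)
    if len(active):
        springs.l0[active] = springs.l0[active] * (1.0 + dt * rate[active])
    return rate
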