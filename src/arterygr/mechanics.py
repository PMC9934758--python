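"""Membrane kinematics, constituent strain energies and stress measures.

The wall is a thin axisymmetric membrane with in-plane deformation
``F = diag(lambda1, lambda2)`` (axial, circumferential).  Each constituent
cohort deposited at time ``tau`` carries its own natural configuration: its
current stretch is the deposition stretch ``G_h`` times the tissue stretch
accrued since deposition.  Strain energies are per unit constituent mass
(J/kg); multiplying by mass per unit reference area and summing cohorts gives
the membrane strain energy ``w`` (J/m²), whose stretch derivatives are the
Cauchy membrane stresses (N/m, force per deformed length):

    T11 = (1/lambda2) dw/dlambda1,   T22 = (1/lambda1) dw/dlambda2.

Dividing by the deformed thickness converts membrane stress to Cauchy stress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: argument cap for the fiber exponentials; beyond this the stretch is
#: unphysical for the calibrated wall and exp() would overflow anyway
_EXP_GUARD = 700.0


class UnphysicalStretchError(OverflowError):
    """Fiber stretch so large the exponential strain energy overflows."""


@dataclass
class DeformationState:
    """Current membrane deformation and geometry.

    lambda1, lambda2
        Axial and circumferential tissue stretches relative to the
        homeostatic configuration (lambda2 = r / r_h).
    r, r_i
        Mean and inner radius (mm).
    h
        Current thickness (um).
    """

    lambda1: float
    lambda2: float
    r: float
    r_i: float
    h: float

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("stretches must be positive")
        if self.r_i <= 0:
            raise ValueError("inner radius must be positive")

    @property
    def J(self) -> float:
        """Areal dilatation of the membrane."""
        return self.lambda1 * self.lambda2


def fiber_stretch(lambda1, lambda2, alpha_deg):
    """Stretch of a fiber at angle ``alpha_deg`` from the axial direction.

    Fibers are material lines fixed in the reference configuration, so
    lambda_fiber = sqrt(lambda1² cos²α + lambda2² sin²α).
    """
    lambda1 = np.asarray(lambda1, dtype=float)
    lambda2 = np.asarray(lambda2, dtype=float)
    if np.any(lambda1 <= 0) or np.any(lambda2 <= 0):
        raise ValueError("stretches must be positive")
    a = np.radians(alpha_deg)
    out = np.sqrt(lambda1**2 * np.cos(a) ** 2 + lambda2**2 * np.sin(a) ** 2)
    return out if out.ndim else float(out)


def cohort_stretch(current_fiber_stretch, deposition_fiber_stretch, G_h):
    """Stretch of a cohort deposited at tissue fiber stretch ``deposition_fiber_stretch``.

    New material is incorporated at its deposition stretch ``G_h`` and then
    follows the tissue:  lambda_n = G_h * current / deposition.
    """
    cur = np.asarray(current_fiber_stretch, dtype=float)
    dep = np.asarray(deposition_fiber_stretch, dtype=float)
    if np.any(cur <= 0) or np.any(dep <= 0) or G_h <= 0:
        raise ValueError("all stretches must be positive")
    out = G_h * cur / dep
    return out if out.ndim else float(out)


def _guard(arg) -> None:
    if np.any(np.asarray(arg) > _EXP_GUARD):
        raise UnphysicalStretchError(
            "exponential strain-energy argument exceeds the overflow guard"
        )


def psi_collagen(lambda_n, c2c: float, c3c: float, compression: str = "as_printed"):
    """Collagen fiber strain energy per unit mass (J/kg).

    ``compression='zero'`` makes compressed fibers (lambda_n < 1) energy-free;
    the default evaluates the (symmetric) exponential law for all stretches.
    """
    lam = np.asarray(lambda_n, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be positive")
    u = (lam**2 - 1.0) ** 2
    _guard(c3c * u)
    psi = c2c / (4.0 * c3c) * (np.exp(c3c * u) - 1.0)
    if compression == "zero":
        psi = np.where(lam < 1.0, 0.0, psi)
    return psi if psi.ndim else float(psi)


def dpsi_collagen(lambda_n, c2c: float, c3c: float, compression: str = "as_printed"):
    """d(psi_collagen)/d(lambda_n)."""
    lam = np.asarray(lambda_n, dtype=float)
    e = lam**2 - 1.0
    _guard(c3c * e**2)
    d = c2c * lam * e * np.exp(c3c * e**2)
    if compression == "zero":
        d = np.where(lam < 1.0, 0.0, d)
    return d if d.ndim else float(d)


def psi_smc(lambda_n1, lambda_n2, c1m: float, c2m: float, c3m: float):
    """Smooth muscle passive strain energy per unit mass (J/kg).

    2D-incompressible neo-Hookean part plus an exponential circumferential
    fiber-like part (SMCs are circumferentially oriented).
    """
    l1 = np.asarray(lambda_n1, dtype=float)
    l2 = np.asarray(lambda_n2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    e = l2**2 - 1.0
    _guard(c3m * e**2)
    iso = c1m / 2.0 * (l1**2 + l2**2 + 1.0 / (l1**2 * l2**2) - 3.0)
    fib = c2m / (4.0 * c3m) * (np.exp(c3m * e**2) - 1.0)
    out = iso + fib
    return out if out.ndim else float(out)


def dpsi_smc_dl2(lambda_n1, lambda_n2, c1m: float, c2m: float, c3m: float):
    """d(psi_smc)/d(lambda_n2)."""
    l1 = np.asarray(lambda_n1, dtype=float)
    l2 = np.asarray(lambda_n2, dtype=float)
    e = l2**2 - 1.0
    _guard(c3m * e**2)
    out = c1m * (l2 - 1.0 / (l1**2 * l2**3)) + c2m * l2 * e * np.exp(c3m * e**2)
    return out if out.ndim else float(out)


def dpsi_smc_dl1(lambda_n1, lambda_n2, c1m: float):
    """d(psi_smc)/d(lambda_n1) (isotropic part only)."""
    l1 = np.asarray(lambda_n1, dtype=float)
    l2 = np.asarray(lambda_n2, dtype=float)
    out = c1m * (l1 - 1.0 / (l1**3 * l2**2))
    return out if out.ndim else float(out)


def psi_elastin(lambda_n1, lambda_n2, c1e: float):
    """Elastin (amorphous, neo-Hookean, 2D-incompressible) energy per unit mass."""
    l1 = np.asarray(lambda_n1, dtype=float)
    l2 = np.asarray(lambda_n2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    out = c1e / 2.0 * (l1**2 + l2**2 + 1.0 / (l1**2 * l2**2) - 3.0)
    return out if out.ndim else float(out)


def dpsi_elastin_dl2(lambda_n1, lambda_n2, c1e: float):
    l1 = np.asarray(lambda_n1, dtype=float)
    l2 = np.asarray(lambda_n2, dtype=float)
    out = c1e * (l2 - 1.0 / (l1**2 * l2**3))
    return out if out.ndim else float(out)


def dpsi_elastin_dl1(lambda_n1, lambda_n2, c1e: float):
    l1 = np.asarray(lambda_n1, dtype=float)
    l2 = np.asarray(lambda_n2, dtype=float)
    out = c1e * (l1 - 1.0 / (l1**3 * l2**2))
    return out if out.ndim else float(out)


def membrane_stress(w, lambda1: float, lambda2: float, step: float = 1e-6):
    """Cauchy membrane stresses (T11, T22) of a scalar energy ``w(l1, l2)``.

    Differentiates ``w`` (membrane strain energy per reference area, J/m²) by
    central finite differences.  The simulation engine assembles these
    derivatives analytically per cohort; this routine is the generic,
    energy-function-agnostic evaluation used for cross-checks and one-off
    analyses.
    """
    dw1 = (w(lambda1 + step, lambda2) - w(lambda1 - step, lambda2)) / (2.0 * step)
    dw2 = (w(lambda1, lambda2 + step) - w(lambda1, lambda2 - step)) / (2.0 * step)
    return dw1 / lambda2, dw2 / lambda1


def cauchy_stresses(T11: float, T22: float, T_act: float, h: float):
    """Convert membrane stresses (N/m) to Cauchy stresses (Pa).

    ``h`` is the current deformed thickness in metres; the active tone acts
    circumferentially only.
    """
    if h <= 0:
        raise ValueError("thickness must be positive")
    return T11 / h, (T22 + T_act) / h


def normalized_wall_shear(eps: float, r_i_ratio: float) -> float:
    """Wall shear stress ratio tau_w / tau_wh = eps / (r_i/r_ih)³.

    Written in ratio form (flow ratio ``eps`` and inner-radius ratio) so the
    blood viscosity and absolute flow never enter.
    """
    if r_i_ratio <= 0:
        raise ValueError("radius ratio must be positive")
    return eps / r_i_ratio**3
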