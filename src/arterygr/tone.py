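"""Smooth muscle active tone.

Shear regulates the tone magnitude through endothelium-derived NO
(dilation, high shear) and ET-1 (constriction, low shear), modeled as a
tanh sigmoid; a parabolic length–tension relation modulates the force with
the *active* stretch, measured against a slowly relaxing active reference
radius r_act that tracks the current radius with rate K_act.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ToneParameters


@dataclass
class ActiveState:
    """Active reference radius (mm) and the resulting active stretch."""

    r_act: float
    lambda2_act: float

    def __post_init__(self) -> None:
        if self.r_act <= 0:
            raise ValueError("r_act must be positive")


def tone_magnitude(smc_mass_ratio, tau_ratio, params: ToneParameters):
    """Tone magnitude S (N/m), decreasing sigmoid in the shear ratio.

    S = 2 S_basal (M/M0) (1 + tanh(−k_ton (τ/τ_h − 1) − tone_offset)),
    bounded in [0, 4 S_basal M/M0].  At homeostasis (both ratios 1) with the
    default offset ln(3/2): S = (16/13) S_basal.
    """
    smc_mass_ratio = np.asarray(smc_mass_ratio, dtype=float)
    if np.any(smc_mass_ratio <= 0):
        raise ValueError("smc_mass_ratio must be positive")
    arg = -params.k_ton * (np.asarray(tau_ratio, dtype=float) - 1.0) - params.tone_offset
    out = 2.0 * params.S_basal * smc_mass_ratio * (1.0 + np.tanh(arg))
    return out if out.ndim else float(out)


def length_tension(lambda2_act, params: ToneParameters):
    """Parabolic length–tension factor, clamped to [0, 1].

    Equals 1 at the stretch of maximal contraction lambda_M and 0 at
    lambda_0; the parabola is clamped at zero outside the active range
    (a muscle cannot push).
    """
    lam = np.asarray(lambda2_act, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("active stretch must be positive")
    f = 1.0 - ((params.lambda_M - lam) / (params.lambda_M - params.lambda_0)) ** 2
    f = np.maximum(f, 0.0)
    return f if f.ndim else float(f)


def update_active_radius(r_act: float, r: float, K_act: float, dt: float) -> float:
    """Exact exponential relaxation of r_act toward r over ``dt`` days."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return r + (r_act - r) * math.exp(-K_act * dt)


def active_membrane_stress(S, lambda2_act, params: ToneParameters):
    """Circumferential active membrane stress T_act = S λ2act f(λ2act) ≥ 0."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("tone magnitude must be non-negative")
    out = S * np.asarray(lambda2_act, dtype=float) * length_tension(lambda2_act, params)
    return out if out.ndim else float(out)


def smc_scalar_stress(T22: float, T_act: float, M_Rm: float,
                      lambda1: float, lambda2: float,
                      phi_f: float, rho: float) -> tuple[float, float]:
    """SMC stress measure sigma_m (Pa) and muscle-attributed thickness h_m (m).

    h_m = M_Rm / ((1 − phi_f) ρ λ1 λ2);  sigma_m = (T22 + T_act) / h_m.
    Which membrane stress enters the numerator (total passive vs the SMC
    contribution alone) is the caller's choice; the engine exposes it as the
    ``smc_stress_numerator`` switch.
    """
    if M_Rm <= 0:
        raise ValueError("M_Rm must be positive")
    h_m = M_Rm / ((1.0 - phi_f) * rho * lambda1 * lambda2)
    return (T22 + T_act) / h_m, h_m


def peak_active_stretch(params: ToneParameters, lo: float | None = None,
                        hi: float | None = None, step: float = 1e-4) -> float:
    """Argmax over λ of λ² f(λ): the stretch of peak active Cauchy stress.

    At fixed tone S and frozen active reference radius, the active Cauchy
    stress S λ_act f(λ_act) / h_m(λ) is proportional to λ² f(λ) because the
    muscle thickness thins as 1/λ.  Grid search; ≈ 2.06 with the calibrated
    length–tension constants.
    """
    lo = params.lambda_0 + step if lo is None else lo
    hi = 2.0 * params.lambda_M - params.lambda_0 if hi is None else hi
    lam = np.arange(lo, hi, step)
    g = lam**2 * length_tension(lam, params)
    return float(lam[np.argmax(g)])
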