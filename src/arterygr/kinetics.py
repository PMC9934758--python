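"""Two-compartment collagen turnover kinetics.

Procollagen is synthesized intracellularly at a mechano-regulated mass rate
``m_p``; a fraction ``beta1`` is secreted and assembles into a soluble,
non-load-bearing *intermediate* pool (microfibrils, tracked as a molar
concentration per reference area ``C_IR``).  Intermediates either cross-link
into mature load-bearing fibers at rate ``beta2`` or are removed at rate
``mu1``; mature fibers are removed at rate ``mu2``:

    dC_I/dt = beta1 m_p / MW − (beta2 + mu1) C_I
    dC_F/dt = beta2 C_I − mu2 C_F

The intermediate pool is carried in molar units and converted with the
collagen molecular weight ``MW`` at both boundaries; because MW enters once
on the way in and once on the way out, mature-mass trajectories are invariant
to its value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import KineticParameters


@dataclass
class CollagenPoolState:
    """Per-fiber-family collagen pools (arrays of length 4).

    C_IR : intermediate molar concentration per reference area (mol/m²)
    m_pR : procollagen mass production rate (kg/m²/day)
    M_R  : mature collagen mass per reference area (kg/m²)
    """

    C_IR: np.ndarray
    m_pR: np.ndarray
    M_R: np.ndarray

    def __post_init__(self) -> None:
        for name in ("C_IR", "m_pR", "M_R"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)


@dataclass
class HomeostaticKinetics:
    """Steady-state rates and pools consistent with a mature mass M_R(0)."""

    m_R0: np.ndarray | float    # maturation mass rate, kg/m²/day
    C_IR0: np.ndarray | float   # intermediate concentration, mol/m²
    m_p0: np.ndarray | float    # procollagen mass rate, kg/m²/day


def procollagen_rate(mass_ratio, sigma_k_ratio, tau_ratio,
                     K_sigma_c, K_tau_c, m_p0_k):
    """Mechano-regulated procollagen synthesis rate.

    Production scales with the collagen mass ratio (more cells, more
    synthesis), increases with intramural stress above its homeostatic value
    and decreases with wall shear above its homeostatic value (NO attenuates,
    ET-1 augments synthesis).  Negative values are clamped to zero: shear can
    at most shut synthesis off, not reverse it.

    The gain terms are in the same units as ``m_p0_k``; the engine passes
    gains pre-multiplied by the homeostatic rate so that the dimensionless
    caption values (0–52) act on production *relative to baseline*.
    """
    mass_ratio = np.asarray(mass_ratio, dtype=float)
    if np.any(mass_ratio <= 0):
        raise ValueError("mass_ratio must be positive")
    raw = mass_ratio * (
        K_sigma_c * (np.asarray(sigma_k_ratio, dtype=float) - 1.0)
        - K_tau_c * (np.asarray(tau_ratio, dtype=float) - 1.0)
        + m_p0_k
    )
    out = np.maximum(raw, 0.0)
    return out if out.ndim else float(out)


def step_intermediate(C_IR, m_pR, params: KineticParameters, dt: float):
    """Advance the intermediate pool by ``dt`` days.

    Exact exponential update of the linear ODE with the production rate
    frozen over the step, so non-negativity holds for any dt:

        C(t+dt) = C e^{−k dt} + (beta1 m_p / MW) / k (1 − e^{−k dt}),
        k = beta2 + mu1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = params.beta2 + params.mu1
    decay = math.exp(-k * dt)
    inflow = params.beta1 * np.asarray(m_pR, dtype=float) / params.MW
    out = np.asarray(C_IR, dtype=float) * decay + inflow / k * (1.0 - decay)
    return out if out.ndim else float(out)


def maturation_rate(C_IR, beta2: float, MW: float):
    """Mass rate of cross-linking into mature fibers: m_R = MW beta2 C_IR."""
    out = MW * beta2 * np.asarray(C_IR, dtype=float)
    return out if out.ndim else float(out)


def homeostatic_init(M_R0, params: KineticParameters,
                     mu2: float | None = None,
                     finite_window: bool = False) -> HomeostaticKinetics:
    """Steady-state production rates and pools for a mature mass ``M_R0``.

        m_R(0)  = mu2 M_R(0)
        C_IR(0) = mu2 M_R(0) / (beta2 MW)
        m_p(0)  = (beta2 + mu1) / (beta1 beta2) * mu2 M_R(0)

    ``mu2`` defaults to the kinetic parameter; the engine passes its
    homeostatic degradation constant instead so the two stay consistent.
    With ``finite_window=True`` all three are scaled by
    ``1 / (1 − e^{−mu2 a_max})`` so that the heredity integral truncated at
    the maximum cohort age reproduces ``M_R0`` exactly (the untruncated
    relations discard the e^{−mu2 a_max} tail of the infinite past).
    """
    M_R0 = np.asarray(M_R0, dtype=float)
    if np.any(M_R0 <= 0):
        raise ValueError("M_R0 must be positive")
    mu2 = params.mu2 if mu2 is None else mu2
    corr = 1.0 / (1.0 - math.exp(-mu2 * params.a_max)) if finite_window else 1.0
    m_R0 = mu2 * M_R0 * corr
    C_IR0 = m_R0 / (params.beta2 * params.MW)
    m_p0 = (params.beta2 + params.mu1) / (params.beta1 * params.beta2) * m_R0
    if M_R0.ndim == 0:
        return HomeostaticKinetics(float(m_R0), float(C_IR0), float(m_p0))
    return HomeostaticKinetics(m_R0, C_IR0, m_p0)


def two_pool_closed_form(m_p_step: float, params: KineticParameters, t):
    """Closed-form response of both pools to a step input from rest.

    For constant ``m_p`` switched on at t = 0 with C_I(0) = C_F(0) = 0:

        C_I(t) = (u/k)(1 − e^{−k t}),                u = beta1 m_p / MW
        C_F(t) = (beta2 u / k) [ (1 − e^{−mu2 t})/mu2
                                 − (e^{−mu2 t} − e^{−k t})/(k − mu2) ]

    with ``k = beta2 + mu1``; the repeated-root case k = mu2 uses the
    limiting formula.  Serves as the independent oracle for the stepping
    scheme used in the simulation.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    t = np.asarray(t, dtype=float)
    k = params.beta2 + params.mu1
    mu2 = params.mu2
    u = params.beta1 * m_p_step / params.MW
    C_I = u / k * (1.0 - np.exp(-k * t))
    if abs(k - mu2) < 1e-12 * max(k, mu2):
        C_F = params.beta2 * u / k * ((1.0 - np.exp(-k * t)) / k - t * np.exp(-k * t))
    else:
        C_F = params.beta2 * u / k * (
            (1.0 - np.exp(-mu2 * t)) / mu2
            - (np.exp(-mu2 * t) - np.exp(-k * t)) / (k - mu2)
        )
    if t.ndim == 0:
        return float(C_I), float(C_F)
    return C_I, C_F


def mean_mature_age(mu2: float) -> float:
    """Mean age of mature collagen under constant removal: 1/mu2 days."""
    if mu2 <= 0:
        raise ValueError("mu2 must be positive")
    return 1.0 / mu2
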