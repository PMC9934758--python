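"""Parameter containers and configuration I/O.

All parameters carry the units in which they are usually reported for a
mouse carotid artery (radii in mm, thickness in μm, pressure in mmHg,
stresses in kPa / Pa); SI conversions are exposed as properties so the
mechanics code works in metres, newtons and pascals throughout.  Time is
measured in days everywhere, matching the turnover rates (day⁻¹).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import yaml

#: Pa per mmHg
MMHG_TO_PA = 133.322

#: Soft-tissue mass density of the hydrated wall, kg/m^3.  Not measured for
#: this vessel; all reported quantities are stress- or ratio-valued and the
#: density cancels between mass-per-area and thickness.
RHO_WALL = 1050.0


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a physical invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class KineticParameters:
    """Two-compartment collagen turnover constants.

    beta1
        Fraction of synthesized procollagen secreted to the extracellular
        space (the rest is degraded intracellularly within minutes).
    beta2
        Rate of cross-linking, i.e. conversion of intermediate microfibrils
        into mature load-bearing fibers (day⁻¹).
    mu1
        Removal rate of the soluble intermediate pool (day⁻¹).
    mu2
        Baseline removal rate of mature cross-linked collagen (day⁻¹);
        the mean fiber age is 1/mu2.
    MW
        Molecular weight of a collagen molecule (kg); converts between molar
        concentration of the intermediate pool and mass rates.
    a_max
        Maximum tracked cohort age (day); older cohorts are dropped.
    """

    beta1: float = 0.7
    beta2: float = 0.2
    mu1: float = 0.1
    mu2: float = 0.01
    MW: float = 4.981617e-22
    a_max: float = 350.0

    def __post_init__(self) -> None:
        _require(0.0 < self.beta1 <= 1.0, "beta1 must lie in (0, 1]")
        _require(self.beta2 > 0 and self.mu2 > 0, "beta2 and mu2 must be positive")
        _require(self.mu1 >= 0, "mu1 must be non-negative")
        _require(self.MW > 0, "MW must be positive")
        if self.a_max < 3.0 / self.mu2:
            warnings.warn(
                "a_max < 3/mu2: the cohort window truncates a non-negligible "
                "fraction of the mature collagen population",
                stacklevel=2,
            )


@dataclass
class WallParameters:
    """Geometry, composition and passive material constants of the wall.

    Defaults are the calibrated mouse carotid values.  Collagen is a
    four-fiber-family network; the family order convention is
    [axial 0°, circumferential 90°, +alpha_h, −alpha_h] with mass fractions
    ``phi0_k`` in the same order.
    """

    r_oh: float = 0.328          # homeostatic outer radius, mm
    h_h: float = 21.2            # homeostatic thickness, um
    alpha_h: float = 47.6        # diagonal fiber angle from the axial direction, deg
    G_hc: float = 1.07           # collagen deposition stretch
    G_hm: float = 1.25           # SMC circumferential deposition stretch
    G1e: float = 2.19            # elastin axial deposition stretch
    G2e: float = 1.64            # elastin circumferential deposition stretch
    c1e: float = 657.9           # elastin neo-Hookean constant, J/kg
    c2c: float = 3090.0          # collagen exponential stiffness, J/kg
    c3c: float = 18.9            # collagen exponential exponent
    c1m: float = 103.0           # SMC neo-Hookean constant, J/kg
    c2m: float = 11.5            # SMC exponential stiffness, J/kg
    c3m: float = 0.794           # SMC exponential exponent
    sigma_h: float = 120.0       # homeostatic intramural stress, kPa
    tau_wh: float = 1.5          # homeostatic wall shear stress, Pa
    P_h: float = 102.0           # homeostatic pressure, mmHg
    phi0_e: float = 0.06         # elastin mass fraction
    phi0_m: float = 0.09         # SMC mass fraction
    phi0_k: tuple[float, float, float, float] = (
        0.15 * 0.111,
        0.15 * 0.0349,
        0.15 * 0.427,
        0.15 * 0.427,
    )                            # collagen family mass fractions (sum 0.15)
    phi_f: float = 0.70          # fluid mass fraction
    rho_wall: float = RHO_WALL   # kg/m^3

    def __post_init__(self) -> None:
        self.phi0_k = tuple(float(p) for p in self.phi0_k)
        _require(len(self.phi0_k) == 4, "phi0_k must have four entries")
        total = self.phi0_e + self.phi0_m + sum(self.phi0_k) + self.phi_f
        _require(abs(total - 1.0) < 1e-3, f"mass fractions must sum to 1 (got {total:.5f})")
        for name in ("G_hc", "G_hm", "G1e", "G2e"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(0 <= self.alpha_h <= 90, "alpha_h must lie in [0, 90] degrees")
        _require(self.h_h * 1e-3 < self.r_oh, "thickness must be smaller than the outer radius")
        _require(self.rho_wall > 0 and 0 <= self.phi_f < 1, "invalid density / fluid fraction")

    # -- SI conversions -------------------------------------------------
    @property
    def r_oh_m(self) -> float:
        return self.r_oh * 1e-3

    @property
    def h_h_m(self) -> float:
        return self.h_h * 1e-6

    @property
    def r_h_m(self) -> float:
        """Homeostatic mean radius (m)."""
        return self.r_oh_m - self.h_h_m / 2.0

    @property
    def r_ih_m(self) -> float:
        """Homeostatic inner radius (m)."""
        return self.r_oh_m - self.h_h_m

    @property
    def P_h_Pa(self) -> float:
        return self.P_h * MMHG_TO_PA

    @property
    def sigma_h_Pa(self) -> float:
        return self.sigma_h * 1e3

    @property
    def alpha_h_rad(self) -> float:
        return math.radians(self.alpha_h)


@dataclass
class ToneParameters:
    """Smooth muscle active tone constants.

    The tone magnitude is a sigmoid in the wall shear stress ratio,
    ``S = 2 S_basal (M/M0) (1 + tanh(−k_ton (τ/τ_h − 1) − tone_offset))``,
    bounded in [0, 4 S_basal M/M0]; ``tone_offset = ln(3/2)`` places the
    homeostatic point below half-maximum so both constriction and dilation
    headroom exist.
    """

    S_basal: float = 0.862       # basal tone magnitude, N/m
    k_ton: float = 52.0 / 3.0    # shear sensitivity (K_tau / 3)
    lambda_M: float = 1.65       # stretch of maximal contraction
    lambda_0: float = 0.65       # stretch of zero contraction
    K_act: float = 0.10          # active-radius relaxation rate, day^-1
    tone_offset: float = math.log(1.5)
    tau_signal: float = 0.0      # shear-signaling (NO/ET-1) response time, day; 0 = instantaneous

    def __post_init__(self) -> None:
        _require(self.lambda_M > self.lambda_0 > 0, "need lambda_M > lambda_0 > 0")
        _require(self.K_act > 0, "K_act must be positive")
        _require(self.S_basal >= 0, "S_basal must be non-negative")
        _require(self.tau_signal >= 0, "tau_signal must be non-negative")


@dataclass
class GainParameters:
    """Mechano-regulation gains for production and degradation.

    ``K_sigma_*`` and ``K_tau_*`` are the dimensionless intramural-stress and
    wall-shear gains on mass production (they scale the homeostatic production
    rate).  ``K_mu1`` is the baseline degradation rate of mature collagen (and
    the constant SMC apoptosis rate) and ``K_mu2`` the quadratic sensitivity of
    collagen degradation to the fiber tension ratio; ``zeta_c`` is the
    homeostatic tension ratio (1 at the deposition stretch).
    """

    K_sigma_c: float = 2.0
    K_sigma_m: float = 2.0
    K_tau_c: float = 52.0
    K_tau_m: float = 52.0
    K_mu1: float = 0.01          # day^-1
    K_mu2: float = 0.01          # day^-1
    zeta_c: float = 1.0

    def __post_init__(self) -> None:
        _require(self.K_mu1 > 0, "K_mu1 must be positive")
        for name in ("K_sigma_c", "K_sigma_m", "K_tau_c", "K_tau_m", "K_mu2"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")


@dataclass
class NumericsOptions:
    """Discretization, solver and model-variant switches."""

    dt: float = 0.1                      # global step, day
    duration: float = 300.0              # simulated time, day
    output_interval: float = 1.0         # recording cadence, day
    newton_tol_scale: float = 1e-9       # residual tol = scale * P_h * r_h
    newton_max_iter: int = 100
    fd_step_scale: float = 1e-7          # Jacobian step = scale * r_h
    collagen_compression: str = "as_printed"  # or "zero": compressed fibers carry no load
    smc_stress_numerator: str = "smc_only"    # or "total": T22 term in the SMC stress measure
    stress_stimulus: str = "constituent"      # or "total_hoop": scalar stress entering production
    tone_balance: str = "absorb"              # or "strict": fail if S_basal adjustment > 5%

    def __post_init__(self) -> None:
        _require(self.dt > 0 and self.duration > 0, "dt and duration must be positive")
        _require(self.output_interval >= self.dt - 1e-12, "output_interval must be >= dt")
        _require(self.collagen_compression in ("as_printed", "zero"),
                 "collagen_compression must be 'as_printed' or 'zero'")
        _require(self.smc_stress_numerator in ("total", "smc_only"),
                 "smc_stress_numerator must be 'total' or 'smc_only'")
        _require(self.stress_stimulus in ("constituent", "total_hoop"),
                 "stress_stimulus must be 'constituent' or 'total_hoop'")
        _require(self.tone_balance in ("absorb", "strict"),
                 "tone_balance must be 'absorb' or 'strict'")


@dataclass
class ModelConfig:
    """Aggregate configuration: the full model definition."""

    kinetics: KineticParameters = field(default_factory=KineticParameters)
    wall: WallParameters = field(default_factory=WallParameters)
    tone: ToneParameters = field(default_factory=ToneParameters)
    gains: GainParameters = field(default_factory=GainParameters)
    numerics: NumericsOptions = field(default_factory=NumericsOptions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wall"]["phi0_k"] = list(d["wall"]["phi0_k"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        sections = {}
        section_types = {
            "kinetics": KineticParameters,
            "wall": WallParameters,
            "tone": ToneParameters,
            "gains": GainParameters,
            "numerics": NumericsOptions,
        }
        for name, typ in section_types.items():
            payload = dict(data.get(name, {}))
            valid = {f.name for f in fields(typ)}
            bad = set(payload) - valid
            if bad:
                raise ConfigurationError(f"unknown keys in [{name}]: {sorted(bad)}")
            sections[name] = typ(**payload)
        return cls(**sections)

    def replace(self, **dotted: float) -> "ModelConfig":
        """Return a copy with ``section.key`` entries overridden.

        Accepts either dotted keys (``gains.K_sigma_c``) or bare keys, which
        are resolved against all sections (must be unambiguous).
        """
        d = self.to_dict()
        for key, value in dotted.items():
            if "." in key:
                section, name = key.split(".", 1)
                if section not in d or name not in d[section]:
                    raise ConfigurationError(f"unknown parameter {key!r}")
                d[section][name] = value
            else:
                hits = [s for s in d if key in d[s]]
                if len(hits) != 1:
                    raise ConfigurationError(
                        f"parameter {key!r} is {'ambiguous' if hits else 'unknown'}"
                    )
                d[hits[0]][key] = value
        return ModelConfig.from_dict(d)


def load_config(path) -> ModelConfig:
    """Read a YAML config file (any subset of sections/keys; rest default)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    return ModelConfig.from_dict(data)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
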