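"""Hemodynamic perturbation scenarios, fixtures, and time-series I/O.

A scenario is a pair of piecewise-linear time courses of the normalized
pressure gamma(t) = P/P_h and normalized flow eps(t) = Q/Q_h.  Both equal 1
at t <= 0 (the homeostatic past); between knots values are interpolated
linearly and after the last knot held constant.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: effectively instantaneous rise time used to encode step changes (day)
_STEP_EPS = 1e-9


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    """Piecewise-linear (t, gamma) and (t, eps) time courses."""

    name: str
    t_gamma: np.ndarray
    v_gamma: np.ndarray
    t_eps: np.ndarray
    v_eps: np.ndarray
    duration: float = 300.0

    def __post_init__(self) -> None:
        for attr in ("t_gamma", "v_gamma", "t_eps", "v_eps"):
            setattr(self, attr, np.atleast_1d(np.asarray(getattr(self, attr), dtype=float)))
        for tname, vname in (("t_gamma", "v_gamma"), ("t_eps", "v_eps")):
            t, v = getattr(self, tname), getattr(self, vname)
            if t.shape != v.shape:
                raise ScenarioError(f"{tname} and {vname} must have equal length")
            if np.any(np.diff(t) < 0):
                raise ScenarioError(f"{tname} must be non-decreasing")
            if np.any(v <= 0):
                raise ScenarioError("gamma and eps must be positive everywhere")

    def gamma(self, t):
        return self._sample(t, self.t_gamma, self.v_gamma)

    def eps(self, t):
        return self._sample(t, self.t_eps, self.v_eps)

    @staticmethod
    def _sample(t, knots_t, knots_v):
        out = np.interp(t, knots_t, knots_v, left=1.0, right=float(knots_v[-1]))
        return float(out) if np.ndim(t) == 0 else out

    def sample(self, t) -> tuple[float, float]:
        return self.gamma(t), self.eps(t)

    def hash(self) -> str:
        payload = np.concatenate([self.t_gamma, self.v_gamma, self.t_eps, self.v_eps,
                                  [self.duration]])
        return hashlib.sha256(payload.tobytes()).hexdigest()[:16]


def _step_knots(magnitude: float, onset: float):
    return np.array([onset, onset + _STEP_EPS]), np.array([1.0, magnitude])


def build_scenario(kind: str, magnitude: float | None = None, onset: float = 0.0,
                   duration: float = 300.0, ramp_days: float = 10.0,
                   path=None) -> Scenario:
    """Construct a scenario.

    kind
        ``step_flow`` / ``step_pressure`` — a step of ``magnitude`` at
        ``onset``; ``ramp_flow`` / ``ramp_pressure`` — linear ramp reaching
        ``magnitude`` over ``ramp_days``; ``csv`` — read knots from ``path``.
    """
    one = np.array([0.0]), np.array([1.0])
    if kind == "step_flow":
        t, v = _step_knots(magnitude, onset)
        return Scenario(f"step_flow_{magnitude:g}", *one, t, v, duration)
    if kind == "step_pressure":
        t, v = _step_knots(magnitude, onset)
        return Scenario(f"step_pressure_{magnitude:g}", t, v, *one, duration)
    if kind == "ramp_flow":
        t = np.array([onset, onset + ramp_days])
        v = np.array([1.0, magnitude])
        return Scenario(f"ramp_flow_{magnitude:g}", *one, t, v, duration)
    if kind == "ramp_pressure":
        t = np.array([onset, onset + ramp_days])
        v = np.array([1.0, magnitude])
        return Scenario(f"ramp_pressure_{magnitude:g}", t, v, *one, duration)
    if kind == "csv":
        if path is None:
            raise ScenarioError("kind='csv' requires a path")
        return read_scenario_csv(path, duration=duration)
    raise ScenarioError(f"unknown scenario kind {kind!r}")


def parse_scenario_name(name: str, duration: float = 300.0) -> Scenario:
    """Resolve names like ``step_flow_0.7`` or ``step_pressure_1.5`` (or a CSV path)."""
    p = Path(name)
    if p.suffix.lower() == ".csv":
        if not p.exists():
            raise ScenarioError(f"scenario file not found: {name}")
        return read_scenario_csv(p, duration=duration)
    for kind in ("step_flow", "step_pressure", "ramp_flow", "ramp_pressure"):
        if name.startswith(kind + "_"):
            try:
                mag = float(name[len(kind) + 1:])
            except ValueError as exc:
                raise ScenarioError(f"cannot parse magnitude in {name!r}") from exc
            return build_scenario(kind, magnitude=mag, duration=duration)
    if name in ("baseline", "homeostatic"):
        return Scenario("baseline", [0.0], [1.0], [0.0], [1.0], duration)
    raise ScenarioError(f"unknown scenario {name!r}")


def ideal_adaptation(gamma: float, eps: float) -> tuple[float, float]:
    """Fully adapted geometry ratios from the cube-root law.

    Restoring the wall shear stress 4µQ/(π r_i³) requires r_i/r_ih = eps^{1/3};
    restoring the hoop stress P r_i / h then requires h/h_h = gamma eps^{1/3}.
    """
    if gamma <= 0 or eps <= 0:
        raise ValueError("gamma and eps must be positive")
    r_ratio = eps ** (1.0 / 3.0)
    return r_ratio, gamma * r_ratio


# ---------------------------------------------------------------------------
# CSV dialect: columns t_day, gamma, eps (header required); linear
# interpolation between rows, constant extrapolation after the last row.
# ---------------------------------------------------------------------------

def write_scenario_csv(scenario: Scenario, path) -> None:
    t = np.union1d(scenario.t_gamma, scenario.t_eps)
    frame = pd.DataFrame({
        "t_day": t,
        "gamma": scenario.gamma(t),
        "eps": scenario.eps(t),
    })
    frame.to_csv(path, index=False)


def read_scenario_csv(path, duration: float = 300.0) -> Scenario:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ScenarioError(f"cannot parse scenario CSV {path}: {exc}") from exc
    cols = [c.strip() for c in frame.columns]
    frame.columns = cols
    if "t_day" not in cols:
        raise ScenarioError(f"{path}: missing required column 't_day'")
    if "gamma" not in cols and "eps" not in cols:
        raise ScenarioError(f"{path}: need at least one of 'gamma'/'eps' columns")
    for i, row in frame.iterrows():
        if row.isna().any():
            raise ScenarioError(f"{path}: malformed value on data line {i + 2}")
    t = frame["t_day"].to_numpy(dtype=float)
    gamma = frame["gamma"].to_numpy(dtype=float) if "gamma" in cols else np.ones_like(t)
    eps = frame["eps"].to_numpy(dtype=float) if "eps" in cols else np.ones_like(t)
    return Scenario(Path(path).stem, t, gamma, t, eps, duration)


def generate_fixture_scenarios(seed: int, outdir) -> list[Path]:
    """Write a deterministic family of synthetic scenario CSVs.

    Includes the canonical steps (eps = 0.7, eps = 1.3, gamma = 1.5) plus
    seeded piecewise-linear flow-decay (ligation-like) and pressure-rise
    (hypertension-like) traces with gamma in [1, 1.65] and eps in [0.3, 1.3].
    These are synthetic stand-ins for measured hemodynamic time courses.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []

    def emit(scn: Scenario, stem: str) -> None:
        p = outdir / f"{stem}.csv"
        write_scenario_csv(scn, p)
        paths.append(p)

    emit(build_scenario("step_flow", 0.7), "step_flow_0.7")
    emit(build_scenario("step_flow", 1.3), "step_flow_1.3")
    emit(build_scenario("step_pressure", 1.5), "step_pressure_1.5")

    for i in range(3):
        knots = np.sort(rng.uniform(1.0, 21.0, size=3))
        target = rng.uniform(0.3, 1.0)
        levels = np.concatenate([[1.0], np.sort(rng.uniform(target, 1.0, size=2))[::-1], [target]])
        t = np.concatenate([[0.0], knots])
        emit(Scenario(f"ligation_like_{i}", [0.0], [1.0], t, levels), f"ligation_like_{i}")
    for i in range(3):
        knots = np.sort(rng.uniform(1.0, 56.0, size=3))
        target = rng.uniform(1.0, 1.65)
        levels = np.concatenate([[1.0], np.sort(rng.uniform(1.0, target, size=2)), [target]])
        t = np.concatenate([[0.0], knots])
        emit(Scenario(f"hypertension_like_{i}", t, levels, [0.0], [1.0]), f"hypertension_like_{i}")
    return paths


# ---------------------------------------------------------------------------
# Simulation time-series output
# ---------------------------------------------------------------------------

#: required output columns, in order
TIMESERIES_COLUMNS = [
    "t_day", "r_mm", "r_i_mm", "h_um", "lambda2", "tau_ratio",
    "sigma1_kPa", "sigma2_kPa", "M_Rc_ratio", "M_Rm_ratio",
    "S_Npm", "T_act_Npm", "C_IR_total",
]


def write_timeseries(result, path) -> None:
    """Write a simulation result as CSV (full repr precision, round-trip exact)."""
    frame = result.frame if hasattr(result, "frame") else result
    if len(frame) == 0:
        raise ValueError("refusing to write an empty time series")
    missing = [c for c in TIMESERIES_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"time series missing columns: {missing}")
    ordered = TIMESERIES_COLUMNS + [c for c in frame.columns if c not in TIMESERIES_COLUMNS]
    frame[ordered].to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    # round_trip parsing so written repr-precision floats come back bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def write_manifest(path, config, scenario: Scenario, dt: float, duration: float,
                   extra: dict | None = None) -> None:
    """Record everything needed to re-run a simulation bit-identically."""
    from . import __version__

    manifest = {
        "arterygr_version": __version__,
        "config": config.to_dict(),
        "scenario": {
            "name": scenario.name,
            "hash": scenario.hash(),
            "t_gamma": scenario.t_gamma.tolist(),
            "v_gamma": scenario.v_gamma.tolist(),
            "t_eps": scenario.t_eps.tolist(),
            "v_eps": scenario.v_eps.tolist(),
        },
        "dt": dt,
        "duration": duration,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
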