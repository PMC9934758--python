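"""Constrained-mixture time-marching engine.

Each global step (default 0.1 day): sample the hemodynamic scenario, solve
the circumferential membrane equilibrium

    P r = T22(r) + S(r) lambda2_act f(lambda2_act)

for the mean radius r by Newton iteration (the tone magnitude S responds to
the shear ratio at the candidate radius; the active reference radius r_act
is frozen during the solve because it relaxes on a 10-day time scale), relax
r_act toward the new radius, evaluate the stress stimuli, advance the
collagen kinetics and SMC production, update every cohort's survival
fraction with its own stress-dependent degradation rate, deposit a new
cohort at the current deformation, and re-assemble masses and stresses.

Constituent strain energy and mass are heredity integrals over past
deposition times: trapezoidal quadrature over the stored cohort grid plus a
closed-form term for the homeostatic past (tau <= 0), which collapses to a
single lumped cohort because all pre-history material shares one deposition
state.  Elastin is a permanent constituent of fixed mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import kinetics, mechanics, tone
from .params import ModelConfig
from .scenarios import Scenario


class SolverError(RuntimeError):
    """Equilibrium radius solve failed; carries a diagnostic state dump."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


def degradation_rate(zeta, K_mu1: float, K_mu2: float, zeta_c: float):
    """Mature-collagen removal rate mu2 = K_mu1 + K_mu2 (zeta − zeta_c)².

    Fibers off their homeostatic tension (slack or overstretched) are
    degraded faster; the rate never falls below the baseline K_mu1.
    """
    out = K_mu1 + K_mu2 * (np.asarray(zeta, dtype=float) - zeta_c) ** 2
    return out if out.ndim else float(out)


def fiber_tension_ratio(cohort_stretch, G_h: float, dpsi):
    """Tension ratio zeta = psi'(lambda_n) / psi'(G_h) of a cohort.

    ``dpsi`` is the fiber energy derivative; the denominator is evaluated at
    the deposition stretch, which must be away from the energy minimum
    (G_h = 1 would make it zero).
    """
    denom = dpsi(G_h)
    if denom == 0:
        raise ValueError("deposition stretch G_h=1 gives zero homeostatic fiber tension")
    out = np.asarray(dpsi(cohort_stretch), dtype=float) / denom
    return out if out.ndim else float(out)


def survival_update(q, mu2_now, dt: float):
    """One-step survival decay q' = q e^{−mu2 dt} (incremental heredity kernel)."""
    out = np.asarray(q, dtype=float) * np.exp(-np.asarray(mu2_now, dtype=float) * dt)
    return out if out.ndim else float(out)


def collagen_scalar_stress(T11_c: float, T22_c: float, directions: np.ndarray,
                           M_Rc: float, lambda1: float, lambda2: float,
                           phi_f: float, rho: float):
    """Per-family collagen stress measure and collagen-attributed thickness.

    ``directions`` are fiber angles (radians from the axial direction);
    sigma^k = |T^c y^k| / h_c with T^c the summed collagen membrane stress
    tensor diag(T11_c, T22_c) and h_c = M_Rc/((1−phi_f) rho lambda1 lambda2).
    """
    if M_Rc <= 0:
        raise ValueError("M_Rc must be positive")
    h_c = M_Rc / ((1.0 - phi_f) * rho * lambda1 * lambda2)
    sigma_k = np.sqrt((T11_c * np.cos(directions)) ** 2
                      + (T22_c * np.sin(directions)) ** 2) / h_c
    return sigma_k, h_c


def smc_production(smc_mass_ratio: float, sigma_m_ratio: float, tau_ratio: float,
                   K_sigma_m: float, K_tau_m: float, m_Rm0: float) -> float:
    """Mechano-regulated smooth muscle production rate, clamped at zero.

    Same structure as the collagen synthesis law: gains are supplied in the
    units of the baseline rate ``m_Rm0`` (the engine passes K·m_Rm0).
    """
    if smc_mass_ratio <= 0:
        raise ValueError("smc_mass_ratio must be positive")
    raw = smc_mass_ratio * (K_sigma_m * (sigma_m_ratio - 1.0)
                            - K_tau_m * (tau_ratio - 1.0) + m_Rm0)
    return max(raw, 0.0)


@dataclass
class CohortHistory:
    """Deposition-time grid state for the load-bearing, turning-over constituents.

    Arrays are preallocated over the full run; column j corresponds to
    deposition time j*dt.  Collagen rows are the four fiber families.
    """

    tau: np.ndarray          # (N+1,) deposition times, day
    m_c: np.ndarray          # (4, N+1) maturation mass rate at deposition, kg/m²/day
    q_c: np.ndarray          # (4, N+1) survival fraction to current time
    lamdep_c: np.ndarray     # (4, N+1) fiber stretch of the tissue at deposition
    m_m: np.ndarray          # (N+1,) SMC production rate
    q_m: np.ndarray          # (N+1,) SMC survival fraction
    lamdep_m: np.ndarray     # (N+1,) circumferential stretch at deposition


@dataclass
class SimulationResult:
    """Recorded time series plus the anchors needed for post-processing."""

    frame: pd.DataFrame
    config: ModelConfig
    scenario: Scenario
    meta: dict = field(default_factory=dict)

    def row_at(self, day: float) -> pd.Series:
        idx = (self.frame["t_day"] - day).abs().idxmin()
        row = self.frame.loc[idx]
        if abs(row["t_day"] - day) > 0.5 * self.meta["output_interval"] + 1e-9:
            raise KeyError(f"no recorded output near day {day}")
        return row


class Engine:
    """One simulation instance (configuration + scenario + preallocated state)."""

    N_FAMILIES = 4

    def __init__(self, config: ModelConfig, scenario: Scenario,
                 dt: float | None = None, duration: float | None = None):
        self.config = config
        self.scenario = scenario
        num = config.numerics
        self.dt = float(num.dt if dt is None else dt)
        self.duration = float(num.duration if duration is None else duration)
        self.n_steps = int(round(self.duration / self.dt))
        if abs(self.n_steps * self.dt - self.duration) > 1e-9 * max(1.0, self.duration):
            raise ValueError("duration must be an integer multiple of dt")

        wall, gains, kin, tn = config.wall, config.gains, config.kinetics, config.tone
        self.wall, self.gains, self.kin = wall, gains, kin

        # geometry (SI)
        self.r_h = wall.r_h_m
        self.h_h = wall.h_h_m
        self.r_ih = wall.r_ih_m
        self.P_h = wall.P_h_Pa

        # fiber families: [axial, circumferential, +alpha, −alpha]
        a = wall.alpha_h_rad
        ang = np.array([0.0, np.pi / 2.0, a, -a])
        self.angles = ang
        self.cos_a = np.cos(ang)
        self.sin_a = np.sin(ang)
        self.cos2 = self.cos_a**2
        self.sin2 = self.sin_a**2

        # homeostatic masses per reference area
        area_mass = wall.rho_wall * self.h_h
        self.M0_c = np.asarray(wall.phi0_k) * area_mass
        self.M0_m = wall.phi0_m * area_mass
        self.M0_e = wall.phi0_e * area_mass
        self.mass_denom = (1.0 - wall.phi_f) * wall.rho_wall  # thickness = M/(denom*J)

        # homeostatic kinetics, corrected for the finite cohort-age window so
        # the truncated heredity integral is exactly stationary
        self.mu2_h = gains.K_mu1
        hk = kinetics.homeostatic_init(self.M0_c, kin, mu2=self.mu2_h, finite_window=True)
        self.m_h_c = np.asarray(hk.m_R0)
        self.C_IR_h = np.asarray(hk.C_IR0)
        self.m_p0_c = np.asarray(hk.m_p0)
        self.mu2_m = gains.K_mu1  # constant SMC apoptosis rate
        self.m_h_m = self.mu2_m * self.M0_m / (1.0 - math.exp(-self.mu2_m * kin.a_max))

        self._dpsi_G = mechanics.dpsi_collagen(
            wall.G_hc, wall.c2c, wall.c3c, config.numerics.collagen_compression)

        self._allocate()
        self.clamp_events = 0
        self.max_abs_residual = 0.0

        # ---- homeostatic anchors and tone balance ----
        self.tone_params = tn
        T = self._assemble(1.0, j=0, t=0.0)
        T22_pass0 = T["T22"]
        f1 = tone.length_tension(1.0, tn)
        T_act_needed = self.P_h * self.r_h - T22_pass0
        S_scale = 2.0 * (1.0 + math.tanh(-tn.tone_offset)) * f1
        S_basal_eff = T_act_needed / S_scale
        adj = S_basal_eff / tn.S_basal - 1.0
        if S_basal_eff <= 0:
            raise SolverError("homeostatic balance requires non-positive basal tone; "
                              "check wall parameters")
        if abs(adj) > 0.05:
            msg = (f"homeostatic balance absorbs a {100*adj:+.1f}% adjustment of "
                   f"S_basal ({tn.S_basal:.3f} -> {S_basal_eff:.3f} N/m)")
            if config.numerics.tone_balance == "strict":
                raise SolverError(msg)
            warnings.warn(msg, stacklevel=2)
        self.S_basal_eff = S_basal_eff
        # effective tone parameter set used everywhere in the engine
        self.tone_eff = tone.ToneParameters(
            S_basal=S_basal_eff, k_ton=tn.k_ton, lambda_M=tn.lambda_M,
            lambda_0=tn.lambda_0, K_act=tn.K_act, tone_offset=tn.tone_offset,
            tau_signal=tn.tau_signal)
        # filtered shear ratio driving the tone (endothelial signaling state)
        self.tau_bar = 1.0

        # the shear ratio is anchored to the model's own t=0 inner radius
        # (printed mass fractions are rounded, so the assembled thickness
        # differs from the printed h_h by ~5e-5 relative)
        h0 = T["M_tot"] / self.mass_denom
        self.r_ih = self.r_h - h0 / 2.0

        # stress-measure anchors (computed homeostatic values)
        self.T_act_h = T_act_needed
        h_c0 = self.M0_c.sum() / self.mass_denom
        h_m0 = self.M0_m / self.mass_denom
        self.sigma_k0 = np.sqrt((T["T11_c"] * self.cos_a) ** 2
                                + (T["T22_c"] * self.sin_a) ** 2) / h_c0
        if config.numerics.smc_stress_numerator == "total":
            self.sigma_m0 = (T22_pass0 + self.T_act_h) / h_m0
        else:
            self.sigma_m0 = (T["T22_m"] + self.T_act_h) / h_m0
        # total hoop Cauchy stress at homeostasis (for the total_hoop stimulus)
        self.sigma2_h = (T22_pass0 + self.T_act_h) / (T["M_tot"] / self.mass_denom)

    # ------------------------------------------------------------------
    # state allocation
    # ------------------------------------------------------------------
    def _allocate(self) -> None:
        N = self.n_steps
        nf = self.N_FAMILIES
        tau = np.arange(N + 1) * self.dt
        self.hist = CohortHistory(
            tau=tau,
            m_c=np.zeros((nf, N + 1)),
            q_c=np.zeros((nf, N + 1)),
            lamdep_c=np.ones((nf, N + 1)),
            m_m=np.zeros(N + 1),
            q_m=np.zeros(N + 1),
            lamdep_m=np.ones(N + 1),
        )
        self.hist.m_c[:, 0] = self.m_h_c
        self.hist.q_c[:, 0] = 1.0
        self.hist.m_m[0] = self.m_h_m
        self.hist.q_m[0] = 1.0
        self.C_IR = self.C_IR_h.copy()

    # ------------------------------------------------------------------
    # heredity-integral assembly
    # ------------------------------------------------------------------
    def _weights(self, j: int, t: float) -> np.ndarray:
        """Trapezoidal weights over stored cohorts 0..j with the age cutoff."""
        w = np.full(j + 1, self.dt)
        w[0] = w[-1] = 0.5 * self.dt
        if j == 0:
            w[0] = 0.0
        age_limit = t - self.kin.a_max
        if age_limit > 0.0:
            tau = self.hist.tau[: j + 1]
            dead = tau < age_limit
            if dead.any():
                w[dead] = 0.0
                k = int(dead.sum())  # first surviving node becomes a boundary
                if k <= j:
                    w[k] = 0.5 * self.dt
        return w

    def _prehistory_mass(self, m_h, mu2_h: float, q0, t: float):
        """Mass of the lumped homeostatic pre-history cohort at time t.

        Integrates m_h e^{mu2_h tau} over tau in [t − a_max, 0] (the surviving
        window of the infinite past) and applies the shared post-t=0 survival
        factor q0, which equals the stored tau=0 cohort's survival because all
        pre-history material has the same deposition state.
        """
        if t >= self.kin.a_max:
            return np.zeros_like(np.asarray(m_h, dtype=float))
        window = (1.0 - math.exp(-mu2_h * (self.kin.a_max - t))) / mu2_h
        return np.asarray(m_h, dtype=float) * np.asarray(q0) * window

    def _assemble(self, lam2: float, j: int, t: float, need_energy: bool = False) -> dict:
        """Membrane stresses, masses and per-cohort stretch data at deformation lam2.

        Uses cohorts deposited at steps 0..j plus the analytic pre-history
        term.  lambda1 = 1 throughout (no axial extension during G&R).
        """
        wall = self.wall
        num = self.config.numerics
        lam1 = 1.0
        sl = slice(0, j + 1)
        wgt = self._weights(j, t)

        # --- collagen, four families at once -------------------------------
        lamk = np.sqrt(lam1**2 * self.cos2 + lam2**2 * self.sin2)        # (4,)
        lam_n = wall.G_hc * lamk[:, None] / self.hist.lamdep_c[:, sl]    # (4, j+1)
        dpsi = mechanics.dpsi_collagen(lam_n, wall.c2c, wall.c3c, num.collagen_compression)
        mq = self.hist.m_c[:, sl] * self.hist.q_c[:, sl] * wgt           # (4, j+1)
        A_c = self._prehistory_mass(self.m_h_c, self.mu2_h, self.hist.q_c[:, 0], t)
        lam_n0 = wall.G_hc * lamk
        dpsi0 = mechanics.dpsi_collagen(lam_n0, wall.c2c, wall.c3c, num.collagen_compression)
        # dw/dlam2 per family: chain rule through lam_n = G lamk / lamdep
        base = (mq * dpsi / self.hist.lamdep_c[:, sl]).sum(axis=1) + A_c * dpsi0
        dlamk_dl2 = lam2 * self.sin2 / lamk
        dlamk_dl1 = lam1 * self.cos2 / lamk
        dw2_c = base * wall.G_hc * dlamk_dl2                             # (4,)
        dw1_c = base * wall.G_hc * dlamk_dl1
        M_c = mq.sum(axis=1) + A_c                                       # (4,)
        T22_c = dw2_c.sum() / lam1
        T11_c = dw1_c.sum() / lam2

        # --- smooth muscle (circumferential) -------------------------------
        lam_n2m = wall.G_hm * lam2 / self.hist.lamdep_m[sl]              # (j+1,)
        dpsim2 = mechanics.dpsi_smc_dl2(1.0, lam_n2m, wall.c1m, wall.c2m, wall.c3m)
        mqm = self.hist.m_m[sl] * self.hist.q_m[sl] * wgt
        A_m = float(self._prehistory_mass(self.m_h_m, self.mu2_m, self.hist.q_m[0], t))
        lam_n2m0 = wall.G_hm * lam2
        dpsim2_0 = mechanics.dpsi_smc_dl2(1.0, lam_n2m0, wall.c1m, wall.c2m, wall.c3m)
        T22_m = ((mqm * dpsim2 / self.hist.lamdep_m[sl]).sum() + A_m * dpsim2_0) \
            * wall.G_hm / lam1
        dpsim1 = mechanics.dpsi_smc_dl1(1.0, lam_n2m, wall.c1m)
        dpsim1_0 = mechanics.dpsi_smc_dl1(1.0, lam_n2m0, wall.c1m)
        T11_m = ((mqm * dpsim1).sum() + A_m * dpsim1_0) / lam2
        M_m = mqm.sum() + A_m

        # --- elastin (permanent, deposition at the reference state) --------
        le1, le2 = wall.G1e * lam1, wall.G2e * lam2
        T22_e = self.M0_e * mechanics.dpsi_elastin_dl2(le1, le2, wall.c1e) * wall.G2e / lam1
        T11_e = self.M0_e * mechanics.dpsi_elastin_dl1(le1, le2, wall.c1e) * wall.G1e / lam2

        out = {
            "lamk": lamk, "lam_n": lam_n, "dpsi": dpsi, "wgt": wgt,
            "T11_c": T11_c, "T22_c": T22_c, "M_c": M_c,
            "T11_m": T11_m, "T22_m": T22_m, "M_m": M_m,
            "T11_e": T11_e, "T22_e": T22_e,
            "T11": T11_c + T11_m + T11_e,
            "T22": T22_c + T22_m + T22_e,
            "M_tot": M_c.sum() + M_m + self.M0_e,
        }
        if need_energy:
            psi = mechanics.psi_collagen(lam_n, wall.c2c, wall.c3c, num.collagen_compression)
            psi0 = mechanics.psi_collagen(lam_n0, wall.c2c, wall.c3c, num.collagen_compression)
            out["w_c"] = (mq * psi).sum(axis=1) + A_c * psi0
            psim = mechanics.psi_smc(1.0, lam_n2m, wall.c1m, wall.c2m, wall.c3m)
            psim0 = mechanics.psi_smc(1.0, lam_n2m0, wall.c1m, wall.c2m, wall.c3m)
            out["w_m"] = (mqm * psim).sum() + A_m * psim0
            out["w_e"] = self.M0_e * mechanics.psi_elastin(le1, le2, wall.c1e)
        return out

    # ------------------------------------------------------------------
    # equilibrium
    # ------------------------------------------------------------------
    def _geometry(self, r: float, M_tot: float) -> tuple[float, float, float]:
        lam2 = r / self.r_h
        h = M_tot / (self.mass_denom * lam2)
        r_i = r - h / 2.0
        return lam2, h, r_i

    def _tone_state(self, r: float, r_i: float, eps: float, M_m: float, r_act: float):
        """Instantaneous shear ratio plus the tone state it drives.

        With a finite signaling time (tau_signal > 0) the tone magnitude
        responds to the filtered shear ratio ``tau_bar`` (frozen during the
        radius solve); with tau_signal = 0 it tracks the instantaneous shear
        at the candidate radius.
        """
        tau_ratio = mechanics.normalized_wall_shear(eps, r_i / self.r_ih)
        tau_for_tone = self.tau_bar if self.tone_eff.tau_signal > 0 else tau_ratio
        S = tone.tone_magnitude(M_m / self.M0_m, tau_for_tone, self.tone_eff)
        lam2_act = r / r_act
        T_act = tone.active_membrane_stress(S, lam2_act, self.tone_eff)
        return tau_ratio, S, lam2_act, T_act

    def _residual(self, r: float, j: int, t: float, gamma: float, eps: float,
                  r_act: float) -> float:
        if r <= 0:
            return -gamma * self.P_h * r  # push the solver back to positive radii
        T = self._assemble(r / self.r_h, j, t)
        _, h, r_i = self._geometry(r, T["M_tot"])
        if r_i <= 0:
            return -gamma * self.P_h * r
        _, _, _, T_act = self._tone_state(r, r_i, eps, T["M_m"], r_act)
        return T["T22"] + T_act - gamma * self.P_h * r

    def solve_equilibrium_radius(self, r_prev: float, j: int, t: float,
                                 gamma: float, eps: float, r_act: float) -> float:
        """Newton solve (numerical Jacobian) for the equilibrium mean radius."""
        num = self.config.numerics
        tol = num.newton_tol_scale * self.P_h * self.r_h
        delta = num.fd_step_scale * self.r_h
        r = r_prev
        for _ in range(num.newton_max_iter):
            R = self._residual(r, j, t, gamma, eps, r_act)
            if abs(R) < tol:
                self.max_abs_residual = max(self.max_abs_residual, abs(R))
                return r
            dR = (self._residual(r + delta, j, t, gamma, eps, r_act)
                  - self._residual(r - delta, j, t, gamma, eps, r_act)) / (2.0 * delta)
            if dR == 0.0:
                break
            step = R / dR
            r_new = r - step
            if not (0.25 * r_prev < r_new < 4.0 * r_prev):
                break
            r = r_new
        # bisection fallback on a bracket around the previous radius
        lo, hi = 0.5 * r_prev, 2.0 * r_prev
        f = lambda x: self._residual(x, j, t, gamma, eps, r_act)
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise SolverError(
                f"no equilibrium bracket at t={t:.3f} day",
                diagnostics={"t": t, "gamma": gamma, "eps": eps, "r_prev": r_prev,
                             "residual_lo": flo, "residual_hi": fhi},
            )
        root = brentq(f, lo, hi, xtol=1e-15, rtol=1e-14)
        self.max_abs_residual = max(self.max_abs_residual, abs(f(root)))
        return root

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------
    def run(self) -> SimulationResult:
        dt = self.dt
        num = self.config.numerics
        gains, kin, wall = self.gains, self.kin, self.wall
        out_every = max(1, int(round(num.output_interval / dt)))

        r = self.r_h
        r_act = self.r_h
        m_last_c = self.m_h_c.copy()
        m_last_m = self.m_h_m
        rows = []
        record = self._record_row
        rows.append(record(0, 0.0, r, r_act, 1.0, 1.0))

        for jnew in range(1, self.n_steps + 1):
            t = jnew * dt
            gamma, eps = self.scenario.sample(t)

            # survival decay over (t-dt, t] with degradation rates evaluated at
            # the start-of-step deformation (first-order splitting; exact at
            # the homeostatic state where zeta = 1 regardless of deformation)
            Tprev = self._assemble(r / self.r_h, jnew - 1, t)
            zeta = Tprev["dpsi"] / self._dpsi_G
            mu2 = degradation_rate(zeta, gains.K_mu1, gains.K_mu2, gains.zeta_c)
            self.hist.q_c[:, : jnew] = survival_update(self.hist.q_c[:, : jnew], mu2, dt)
            self.hist.q_m[: jnew] *= math.exp(-self.mu2_m * dt)

            # deposit a provisional cohort for the material produced during
            # the step: last step's production rate, natural configuration at
            # the start-of-step deformation (refined after the solve)
            self.hist.m_c[:, jnew] = m_last_c
            self.hist.q_c[:, jnew] = 1.0
            self.hist.lamdep_c[:, jnew] = Tprev["lamk"]
            self.hist.m_m[jnew] = m_last_m
            self.hist.q_m[jnew] = 1.0
            self.hist.lamdep_m[jnew] = r / self.r_h

            # equilibrium radius (tone responds to shear inside the residual;
            # r_act is frozen: it relaxes on the 1/K_act = 10 day scale)
            try:
                r = self.solve_equilibrium_radius(r, jnew, t, gamma, eps, r_act)
            except SolverError as exc:
                exc.diagnostics["step"] = jnew
                self._dump_failure(rows)
                raise
            lam2 = r / self.r_h

            # the cohort deposited during this step is incorporated at its
            # deposition stretch in the *solved* configuration
            T0 = self._assemble(lam2, jnew, t)
            self.hist.lamdep_c[:, jnew] = T0["lamk"]
            self.hist.lamdep_m[jnew] = lam2

            # active reference radius relaxes toward the new radius
            r_act = tone.update_active_radius(r_act, r, self.tone_eff.K_act, dt)

            # stimuli at the solved state; the shear-signaling state relaxes
            # toward the realized shear ratio before the tone is evaluated
            T = self._assemble(lam2, jnew, t)
            _, h, r_i = self._geometry(r, T["M_tot"])
            if self.tone_eff.tau_signal > 0:
                tau_now = mechanics.normalized_wall_shear(eps, r_i / self.r_ih)
                self.tau_bar = tau_now + (self.tau_bar - tau_now) * math.exp(
                    -dt / self.tone_eff.tau_signal)
            tau_ratio, S, lam2_act, T_act = self._tone_state(r, r_i, eps, T["M_m"], r_act)
            if num.stress_stimulus == "total_hoop":
                sigma2_ratio = (T["T22"] + T_act) / h / self.sigma2_h
                sigma_k_ratio = np.full(self.N_FAMILIES, sigma2_ratio)
                sigma_m_ratio = sigma2_ratio
            else:
                sigma_k, _ = collagen_scalar_stress(
                    T["T11_c"], T["T22_c"], self.angles, float(T["M_c"].sum()),
                    1.0, lam2, wall.phi_f, wall.rho_wall)
                sigma_k_ratio = sigma_k / self.sigma_k0
                T22_for_m = T["T22"] if num.smc_stress_numerator == "total" else T["T22_m"]
                sigma_m, _ = tone.smc_scalar_stress(
                    T22_for_m, T_act, T["M_m"], 1.0, lam2, wall.phi_f, wall.rho_wall)
                sigma_m_ratio = sigma_m / self.sigma_m0

            # production and pools (gains act on production relative to baseline)
            mass_ratio_c = T["M_c"].sum() / self.M0_c.sum()
            m_p = kinetics.procollagen_rate(
                mass_ratio_c, sigma_k_ratio, tau_ratio,
                gains.K_sigma_c * self.m_p0_c, gains.K_tau_c * self.m_p0_c, self.m_p0_c)
            self.clamp_events += int(np.count_nonzero(m_p == 0.0))
            self.C_IR = kinetics.step_intermediate(self.C_IR, m_p, kin, dt)
            m_new_c = kinetics.maturation_rate(self.C_IR, kin.beta2, kin.MW)
            mass_ratio_m = T["M_m"] / self.M0_m
            m_new_m = smc_production(
                mass_ratio_m, sigma_m_ratio, tau_ratio,
                gains.K_sigma_m * self.m_h_m, gains.K_tau_m * self.m_h_m, self.m_h_m)
            if m_new_m == 0.0:
                self.clamp_events += 1

            # the provisional cohort's rate becomes this step's computed rate
            self.hist.m_c[:, jnew] = m_new_c
            self.hist.m_m[jnew] = m_new_m
            m_last_c = m_new_c
            m_last_m = m_new_m

            if jnew % out_every == 0 or jnew == self.n_steps:
                rows.append(record(jnew, t, r, r_act, gamma, eps))

        frame = pd.DataFrame(rows)
        meta = {
            "r_h_m": self.r_h, "r_ih_m": self.r_ih, "h_h_m": self.h_h,
            "M0_c_total": float(self.M0_c.sum()), "M0_m": self.M0_m,
            "mass_denom": self.mass_denom,
            "S_basal_eff": self.S_basal_eff,
            "sigma_k0_Pa": self.sigma_k0.tolist(), "sigma_m0_Pa": self.sigma_m0,
            "dt": self.dt, "duration": self.duration,
            "output_interval": out_every * dt,
            "clamp_events": self.clamp_events,
            "max_abs_residual_Npm": self.max_abs_residual,
            "residual_tol_Npm": num.newton_tol_scale * self.P_h * self.r_h,
        }
        return SimulationResult(frame, self.config, self.scenario, meta)

    def _record_row(self, jnew: int, t: float, r: float, r_act: float,
                    gamma: float, eps: float) -> dict:
        lam2 = r / self.r_h
        T = self._assemble(lam2, jnew, t)
        _, h, r_i = self._geometry(r, T["M_tot"])
        tau_ratio, S, lam2_act, T_act = self._tone_state(r, r_i, eps, T["M_m"], r_act)
        sigma1, sigma2 = mechanics.cauchy_stresses(T["T11"], T["T22"], T_act, h)
        return {
            "t_day": t,
            "r_mm": r * 1e3,
            "r_i_mm": r_i * 1e3,
            "h_um": h * 1e6,
            "lambda2": lam2,
            "tau_ratio": tau_ratio,
            "sigma1_kPa": sigma1 / 1e3,
            "sigma2_kPa": sigma2 / 1e3,
            "M_Rc_ratio": float(T["M_c"].sum() / self.M0_c.sum()),
            "M_Rm_ratio": float(T["M_m"] / self.M0_m),
            "S_Npm": S,
            "T_act_Npm": T_act,
            "C_IR_total": float(self.C_IR.sum()),
            "r_act_mm": r_act * 1e3,
            "gamma": gamma,
            "eps": eps,
        }

    def _dump_failure(self, rows) -> None:
        try:
            pd.DataFrame(rows).to_csv("arterygr_failure_dump.csv", index=False)
        except OSError:
            pass

    # ------------------------------------------------------------------
    # cross-check helpers (independent re-integration)
    # ------------------------------------------------------------------
    def brute_force_masses(self, j: int, t: float) -> tuple[np.ndarray, float]:
        """Re-integrate Eq-20-style masses with an explicit python loop.

        Independent of the vectorized quadrature in ``_assemble``; used by the
        verification suite.
        """
        M_c = np.zeros(self.N_FAMILIES)
        wgt = self._weights(j, t)
        for k in range(self.N_FAMILIES):
            acc = 0.0
            for i in range(j + 1):
                acc += self.hist.m_c[k, i] * self.hist.q_c[k, i] * wgt[i]
            M_c[k] = acc + self._prehistory_mass(self.m_h_c[k], self.mu2_h,
                                                 self.hist.q_c[k, 0], t)
        M_m = 0.0
        for i in range(j + 1):
            M_m += self.hist.m_m[i] * self.hist.q_m[i] * wgt[i]
        M_m += self._prehistory_mass(self.m_h_m, self.mu2_m, self.hist.q_m[0], t)
        return M_c, float(M_m)

    def collagen_energy(self, lam2: float, j: int, t: float) -> np.ndarray:
        """Per-family collagen strain energy per reference area (J/m²)."""
        return self._assemble(lam2, j, t, need_energy=True)["w_c"]


def simulate(scenario: Scenario, config: ModelConfig | None = None,
             dt: float | None = None, duration: float | None = None) -> SimulationResult:
    """Run a growth-and-remodeling simulation of the given scenario."""
    config = config if config is not None else ModelConfig()
    return Engine(config, scenario, dt=dt, duration=duration).run()


def active_stress_sweep(result: SimulationResult, day: float,
                        lam2_grid: np.ndarray | None = None):
    """Active Cauchy stress vs circumferential stretch at a recorded day.

    The tone magnitude S, the active reference radius and the SMC mass are
    frozen at their simulated values on ``day`` while the circumferential
    stretch is swept; the active stretch follows as lam2_act = lam2 r_h/r_act
    and the muscle thickness thins as 1/lam2.  Returns (lam2_grid, sigma_act)
    with sigma_act in kPa.
    """
    tn = result.config.tone
    if lam2_grid is None:
        lam2_grid = np.arange(0.66, 2.80001, 0.01)
    row = result.row_at(day)
    S = row["S_Npm"]
    r_act = row["r_act_mm"] * 1e-3
    M_Rm = row["M_Rm_ratio"] * result.meta["M0_m"]
    r_h = result.meta["r_h_m"]
    tone_eff = tone.ToneParameters(
        S_basal=result.meta["S_basal_eff"], k_ton=tn.k_ton, lambda_M=tn.lambda_M,
        lambda_0=tn.lambda_0, K_act=tn.K_act, tone_offset=tn.tone_offset)
    lam2_act = lam2_grid * r_h / r_act
    T_act = tone.active_membrane_stress(np.full_like(lam2_grid, S), lam2_act, tone_eff)
    h_m = M_Rm / (result.meta["mass_denom"] * lam2_grid)
    return lam2_grid, T_act / h_m / 1e3
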