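"""Constrained-mixture engine: cohorts, heredity integrals, equilibrium, marching."""

import math

import numpy as np
import pytest

from arterygr import ModelConfig, build_scenario
from arterygr.engine import (
    Engine,
    collagen_scalar_stress,
    degradation_rate,
    fiber_tension_ratio,
    smc_production,
    survival_update,
)
from arterygr.mechanics import dpsi_collagen

from conftest import run_quiet

C2C, C3C = 3090.0, 18.9


class TestDegradation:
    def test_baseline_at_homeostatic_tension(self):
        assert degradation_rate(1.0, 0.01, 0.01, 1.0) == pytest.approx(0.01)

    def test_quadratic_growth(self):
        assert degradation_rate(2.0, 0.01, 0.01, 1.0) == pytest.approx(0.02)
        assert degradation_rate(0.0, 0.01, 0.01, 1.0) == pytest.approx(0.02)

    def test_never_below_baseline(self):
        z = np.linspace(-2, 5, 100)
        assert np.all(degradation_rate(z, 0.01, 0.01, 1.0) >= 0.01)


class TestFiberTension:
    def test_unity_at_deposition_stretch(self):
        dpsi = lambda l: dpsi_collagen(l, C2C, C3C)
        assert fiber_tension_ratio(1.07, 1.07, dpsi) == pytest.approx(1.0)

    def test_monotone_above_one(self):
        dpsi = lambda l: dpsi_collagen(l, C2C, C3C)
        lams = np.linspace(1.07, 1.15, 20)
        zetas = fiber_tension_ratio(lams, 1.07, dpsi)
        assert np.all(np.diff(zetas) > 0)
        assert np.all(zetas >= 1.0)

    def test_matches_finite_difference(self):
        dpsi = lambda l: dpsi_collagen(l, C2C, C3C)
        h = 1e-7
        for lam in (1.02, 1.07, 1.12):
            fd = (C2C / (4 * C3C) * (np.exp(C3C * ((lam + h) ** 2 - 1) ** 2) - 1)
                  - C2C / (4 * C3C) * (np.exp(C3C * ((lam - h) ** 2 - 1) ** 2) - 1)) / (2 * h)
            assert fiber_tension_ratio(lam, 1.07, dpsi) == pytest.approx(
                fd / dpsi(1.07), rel=1e-6)

    def test_unit_deposition_stretch_rejected(self):
        dpsi = lambda l: dpsi_collagen(l, C2C, C3C)
        with pytest.raises(ValueError):
            fiber_tension_ratio(1.05, 1.0, dpsi)


class TestSurvival:
    def test_fresh_cohort(self):
        assert survival_update(1.0, 0.01, 0.0 + 1e-300) == pytest.approx(1.0)

    def test_half_life(self):
        q = survival_update(1.0, 0.01, math.log(2) / 0.01)
        assert q == pytest.approx(0.5, rel=1e-12)

    def test_max_age_survival(self):
        assert survival_update(1.0, 0.01, 350.0) == pytest.approx(math.exp(-3.5), rel=1e-12)
        assert math.exp(-3.5) == pytest.approx(0.030, abs=5e-4)


class TestScalarStressMeasures:
    def test_collagen_scalar_stress_arithmetic(self):
        ang = np.array([0.0, np.pi / 2])
        sig, h_c = collagen_scalar_stress(2.0, 3.0, ang, 3.3e-3, 1.0, 1.0, 0.7, 1050.0)
        assert h_c == pytest.approx(3.3e-3 / (0.3 * 1050.0))
        assert sig[0] == pytest.approx(2.0 / h_c)   # axial family sees T11
        assert sig[1] == pytest.approx(3.0 / h_c)   # circumferential sees T22
        # stress scales inversely with the collagen-attributed thickness
        sig2, _ = collagen_scalar_stress(2.0, 3.0, ang, 6.6e-3, 1.0, 1.0, 0.7, 1050.0)
        assert sig2[0] == pytest.approx(sig[0] / 2)

    def test_smc_production_baseline_gain_and_clamp(self):
        m0 = 2.0e-5
        assert smc_production(1.0, 1.0, 1.0, 2 * m0, 52 * m0, m0) == pytest.approx(m0)
        up = smc_production(1.0, 1.1, 1.0, 2 * m0, 52 * m0, m0)
        assert up == pytest.approx(1.2 * m0)
        assert smc_production(1.0, 1.0, 1.2, 2 * m0, 52 * m0, m0) == 0.0


@pytest.fixture(scope="module")
def engine(config):
    return Engine(config, build_scenario("step_flow", 1.0), duration=1.0)


class TestHomeostaticAssembly:
    def test_collagen_stress_anchors_match_reported_homeostatic_stress(self, engine):
        """Per-family collagen stress measures assemble to ~120 kPa at baseline."""
        assert np.allclose(engine.sigma_k0 / 1e3, 120.0, rtol=3e-3)

    def test_smc_anchor_near_homeostatic_stress(self, engine):
        assert engine.sigma_m0 / 1e3 == pytest.approx(120.0, rel=0.03)

    def test_homeostatic_energy_closed_form(self, engine):
        """At steady state the heredity energy is M_R(0) * psi(G) per family."""
        w = engine.collagen_energy(1.0, 0, 0.0)
        psi_G = C2C / (4 * C3C) * (np.exp(C3C * (1.07**2 - 1) ** 2) - 1)
        assert np.allclose(w, engine.M0_c * psi_G, rtol=1e-12)

    def test_homeostatic_mass_equals_initial(self, engine):
        T = engine._assemble(1.0, 0, 0.0)
        assert np.allclose(T["M_c"], engine.M0_c, rtol=1e-12)
        assert T["M_m"] == pytest.approx(engine.M0_m, rel=1e-12)

    def test_tone_balance_closes_equilibrium(self, engine):
        R = engine._residual(engine.r_h, 0, 0.0, 1.0, 1.0, engine.r_h)
        assert abs(R) < 1e-9 * engine.P_h * engine.r_h


class TestMembraneStressDualRoute:
    def test_analytic_t22_matches_energy_finite_difference(self, config):
        """Assembled T22 equals the central difference of the total energy."""
        eng = Engine(config, build_scenario("step_flow", 0.8), duration=5.0)
        eng.run()
        j, t = eng.n_steps, 5.0
        h = 1e-6
        for lam2 in (0.95, 1.0, 1.05):
            T = eng._assemble(lam2, j, t)

            def w(l2):
                out = eng._assemble(l2, j, t, need_energy=True)
                return out["w_c"].sum() + out["w_m"] + out["w_e"]

            fd = (w(lam2 + h) - w(lam2 - h)) / (2 * h)
            assert T["T22"] == pytest.approx(fd, rel=1e-6)

    def test_vectorized_masses_match_python_loop(self, config):
        eng = Engine(config, build_scenario("step_flow", 0.7), duration=10.0)
        eng.run()
        M_c, M_m = eng.brute_force_masses(eng.n_steps, 10.0)
        T = eng._assemble(1.0, eng.n_steps, 10.0)
        assert np.allclose(T["M_c"], M_c, rtol=1e-12)
        assert T["M_m"] == pytest.approx(M_m, rel=1e-12)

    def test_quadrature_refinement(self, config):
        """Halving dt changes the heredity mass by well under 0.1%."""
        masses = []
        for dt in (0.1, 0.05):
            eng = Engine(config, build_scenario("step_flow", 0.7), dt=dt, duration=20.0)
            res = eng.run()
            masses.append(res.frame["M_Rc_ratio"].iloc[-1])
        assert masses[0] == pytest.approx(masses[1], rel=1e-3)


class TestEquilibriumSolve:
    def test_homeostatic_fixed_point_radius(self, engine):
        r = engine.solve_equilibrium_radius(engine.r_h * 1.01, 0, 0.0, 1.0, 1.0, engine.r_h)
        assert r == pytest.approx(engine.r_h, rel=1e-8)

    @pytest.mark.parametrize("gamma, eps", [(1.2, 1.0), (1.0, 0.85), (1.1, 1.15)])
    def test_against_dense_grid_scan(self, config, gamma, eps):
        """Newton root agrees with a brute-force scan of the residual's zero."""
        eng = Engine(config, build_scenario("step_flow", 1.0), duration=1.0)
        r = eng.solve_equilibrium_radius(eng.r_h, 0, 0.0, gamma, eps, eng.r_h)
        grid = np.linspace(0.8 * eng.r_h, 1.2 * eng.r_h, 4001)
        res = np.array([eng._residual(x, 0, 0.0, gamma, eps, eng.r_h) for x in grid])
        sign_flip = np.where(np.diff(np.sign(res)) != 0)[0]
        assert len(sign_flip) >= 1
        bracket_lo, bracket_hi = grid[sign_flip[0]], grid[sign_flip[0] + 1]
        assert bracket_lo <= r <= bracket_hi
        assert abs(eng._residual(r, 0, 0.0, gamma, eps, eng.r_h)) < 1e-9 * eng.P_h * eng.r_h


class TestTimeMarching:
    def test_homeostatic_fixed_point_300_days(self, homeostatic_run):
        """No perturbation: every recorded variable stays put to < 1e-6."""
        f = homeostatic_run.frame
        for col in ("r_mm", "r_i_mm", "h_um", "tau_ratio", "sigma1_kPa", "sigma2_kPa",
                    "M_Rc_ratio", "M_Rm_ratio", "S_Npm", "T_act_Npm", "C_IR_total"):
            drift = np.abs(f[col] / f[col].iloc[0] - 1.0).max()
            assert drift < 1e-6, f"{col} drifted by {drift:.2e}"

    def test_newton_residual_below_tolerance_every_step(self, flow_decrease_run):
        meta = flow_decrease_run.meta
        assert meta["max_abs_residual_Npm"] < meta["residual_tol_Npm"]

    def test_dt_refinement_on_flow_step(self, config):
        """dt=0.1 vs dt=0.05 endpoints differ by < 0.1% (first-order splitting)."""
        ends = []
        for dt in (0.1, 0.05):
            f = run_quiet(build_scenario("step_flow", 0.7), config, dt=dt,
                          duration=60.0).frame
            ends.append((f["r_i_mm"].iloc[-1], f["h_um"].iloc[-1]))
        assert ends[0][0] == pytest.approx(ends[1][0], rel=1e-3)
        assert ends[0][1] == pytest.approx(ends[1][1], rel=1e-3)

    def test_fine_step_oracle_on_perturbed_run(self, config):
        """A 20x finer integration reproduces the same 30-day state to < 1e-3."""
        coarse = run_quiet(build_scenario("step_flow", 0.8), config, dt=0.1,
                           duration=30.0).frame.iloc[-1]
        fine = run_quiet(build_scenario("step_flow", 0.8), config, dt=0.005,
                         duration=30.0).frame.iloc[-1]
        for col in ("r_i_mm", "h_um", "M_Rc_ratio", "M_Rm_ratio"):
            assert coarse[col] == pytest.approx(fine[col], rel=1e-3)

    def test_flow_decrease_adapts_to_cube_root_radius(self, flow_decrease_run):
        f = flow_decrease_run.frame
        ri = f["r_i_mm"].iloc[-1] / f["r_i_mm"].iloc[0]
        assert ri == pytest.approx(0.7 ** (1 / 3), rel=0.01)
        assert f["tau_ratio"].iloc[-1] == pytest.approx(1.0, abs=0.01)

    def test_flow_increase_adapts_to_cube_root_radius(self, flow_increase_run):
        f = flow_increase_run.frame
        ri = f["r_i_mm"].iloc[-1] / f["r_i_mm"].iloc[0]
        assert ri == pytest.approx(1.3 ** (1 / 3), rel=0.01)
        assert f["tau_ratio"].iloc[-1] == pytest.approx(1.0, abs=0.01)

    def test_pressure_step_preserves_lumen_and_thickens(self, pressure_run):
        f = pressure_run.frame
        assert f["r_i_mm"].iloc[-1] / f["r_i_mm"].iloc[0] == pytest.approx(1.0, abs=0.02)
        assert f["h_um"].iloc[-1] > 1.4 * f["h_um"].iloc[0]
        assert f["M_Rc_ratio"].iloc[-1] > 1.5

    def test_masses_and_survivals_stay_physical(self, pressure_run, flow_increase_run):
        for res in (pressure_run, flow_increase_run):
            f = res.frame
            assert (f["M_Rc_ratio"] > 0).all()
            assert (f["M_Rm_ratio"] > 0).all()
            assert (f["h_um"] > 0).all()
            assert (f["T_act_Npm"] >= 0).all()
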