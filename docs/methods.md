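# Methods

This note documents the model implemented in `arterygr`: its equations and
assumptions, parameter provenance, the numerical scheme, the design choices
made where the formulation was genuinely open, and its known limitations.

## Wall model

The artery is an axisymmetric thin-walled (membrane) cylinder. The reference
configuration is the homeostatic in-vivo state: mean radius
r_h = r_oh − h_h/2, thickness h_h, loaded at pressure P_h with wall shear
stress τ_wh. Deformation is `F = diag(λ₁, λ₂)` with λ₂ = r/r_h; the axial
stretch is held at λ₁ = 1 throughout G&R (the vessel is tethered), so the
mean radius is the only mechanical unknown. Axial quantities (T₁₁, σ₁) are
reported as outputs only.

Constituents: elastin (amorphous, permanent — it neither turns over nor
remodels on these timescales), four collagen fiber families, and
circumferentially oriented smooth muscle (SMC). A fiber at angle α from the
axial direction is a material line: λ_fiber = √(λ₁²cos²α + λ₂²sin²α). The
family order convention is [axial 0°, circumferential 90°, +α_h, −α_h] with
mass fractions 0.15·{0.111, 0.0349, 0.427, 0.427}. The fractions are printed
without direction labels; this assignment is validated by the homeostatic
consistency check below.

### Constrained-mixture kinematics

Material incorporated at time τ is deposited under a preferred stretch G_h
(collagen 1.07, SMC 1.25 circumferentially with axial deposition stretch 1,
elastin (2.19, 1.64) relative to the reference state). A cohort's current
stretch is

    λ_n(t) = G_h · λ_fiber(t) / λ_fiber(τ),

so freshly deposited material is load-bearing at its preferred tension
regardless of the current geometry — the mechanism that lets the adapted
state become the new homeostatic state.

### Strain energies (per unit constituent mass, J/kg)

    collagen:  Ψᶜ(λ) = c₂ᶜ/(4c₃ᶜ) [exp(c₃ᶜ(λ²−1)²) − 1]
    SMC:       Ψᵐ = c₁ᵐ/2 (λ₁²+λ₂²+1/(λ₁²λ₂²)−3) + c₂ᵐ/(4c₃ᵐ)[exp(c₃ᵐ(λ₂²−1)²)−1]
    elastin:   Ψᵉ = c₁ᵉ/2 (λ₁²+λ₂²+1/(λ₁²λ₂²)−3)

The collagen law is symmetric in (λ²−1)², so compressed fibers would bear
load; the calibrated simulations never compress fibers below ≈0.96, and the
law is evaluated as written by default. A config switch
(`numerics.collagen_compression = "zero"`) makes compressed fibers
energy-free for sensitivity studies. Arguments of the exponentials are
guarded at 700; beyond that the stretch is unphysical for this wall and an
error is raised rather than silently overflowing.

### Heredity integrals and survival

Strain energy per reference area and mass per reference area of each
turning-over constituent are integrals over the surviving deposition history
with maximum cohort age a_max = 350 days:

    w(t) = ∫ m_R(τ) q(t,τ) Ψ(λ_n(t)) dτ,    M_R(t) = ∫ m_R(τ) q(t,τ) dτ,
    q(t,τ) = exp(−∫_τ^t μ₂(s) ds).

The collagen removal rate is tension-mediated and cohort-specific:

    μ₂ᵏ = K_μ1 + K_μ2 (ζ − ζ_c)²,    ζ = Ψ'(λ_n)/Ψ'(G_h),  ζ_c = 1,

so cohorts displaced from their deposition tension — slack or overstretched —
are cleared faster, with a floor at K_μ1 = 0.01/day. SMC apoptosis is
constant at the same baseline rate. ζ_c = 1 makes μ₂ = K_μ1 at homeostasis,
consistent with the collagen kinetic constant μ₂ = 0.01/day.

Membrane stresses are T₁₁ = (1/λ₂)∂w/∂λ₁ and T₂₂ = (1/λ₁)∂w/∂λ₂, assembled
from analytic per-cohort chain-rule derivatives (a central-finite-difference
evaluation of the assembled energy is kept as an independent cross-check in
the test suite). Cauchy stresses are σ = T/h with
h = M_total/((1−φ_f) ρ λ₁ λ₂); the fluid fraction φ_f = 0.70 and the wall
density ρ = 1050 kg/m³ (standard soft-tissue value; it cancels out of every
ratio- or stress-valued output).

### Active tone

    T_act = S λ₂ᵃᶜᵗ f(λ₂ᵃᶜᵗ)   (circumferential only)
    S = 2 S_basal (M_m/M_m(0)) (1 + tanh(−k_ton(τ_w/τ_wh − 1) − ln 3/2))
    f(λ) = max(0, 1 − ((λ_M − λ)/(λ_M − λ_0))²),  λ_M = 1.65, λ_0 = 0.65
    dr_act/dt = K_act (r − r_act),  λ₂ᵃᶜᵗ = r/r_act,  K_act = 0.1/day

Low shear (ET-1) constricts, high shear (NO) dilates; S is bounded in
[0, 4 S_basal M_m/M_m(0)]. The offset ln(3/2) places the homeostatic point
below half-maximum (tanh(−ln 3/2) = −5/13 exactly), leaving headroom in both
directions; it is configurable (`tone.tone_offset`). The shear sensitivity is
k_ton = K_τw/3 = 52/3, the only reading consistent across the reference
parameter sets. f is clamped at zero outside the active range (muscle cannot
push). An optional first-order lag of the shear signal driving S
(`tone.tau_signal`, modeling the NO/ET-1 signaling time) is provided but
defaults to 0 (instantaneous coupling).

## Collagen turnover chemistry

Per fiber family, procollagen synthesis is mechano-regulated:

    m_p = (M_Rc/M_Rc(0)) · m_p(0) · max(0, K_σᶜ(σᵏ/σᵏ(0) − 1) − K_τwᶜ(τ_w/τ_wh − 1) + 1).

The gain constants K are dimensionless and act on production *relative to its
homeostatic rate* — the only dimensionally consistent reading of gains quoted
as order-1 to order-50 numbers. The mass-ratio prefactor models cell number
scaling with tissue mass. Production is clamped at zero: high shear (NO) can
shut synthesis off but not reverse it; clamp events are counted in the run
metadata. A secreted fraction β₁ = 0.7 enters the intermediate (microfibril)
pool, carried in molar units per reference area:

    dC_I/dt = β₁ m_p /MW − (β₂ + μ₁) C_I,     m_R = MW β₂ C_I,

with β₂ = 0.2/day (cross-linking), μ₁ = 0.1/day (intermediate clearance),
MW = 4.981617e−22 kg. Because MW converts at both boundaries, mature-mass
trajectories are invariant to it (tested). SMC production follows the same
form with its own gains and the SMC stress measure below.

Homeostatic initialization solves the stationary conditions exactly:
m_R(0) = μ₂ M_R(0), C_I(0) = μ₂M_R(0)/(β₂MW),
m_p(0) = (β₂+μ₁)/(β₁β₂) μ₂ M_R(0). Because the heredity integrals are
truncated at a_max, the engine scales these by 1/(1 − e^{−μ₂ a_max}) (≈ +3%)
so the truncated integrals reproduce M_R(0) exactly and the homeostatic state
is an exact fixed point of the discrete scheme for all time, including past
t = a_max when stored cohorts begin to expire.

## Stress measures and their set points

Collagen:  σᵏ = |Tᶜ yᵏ| / h_c with Tᶜ the summed collagen membrane stress,
yᵏ the family direction, and h_c = M_Rc/((1−φ_f)ρλ₁λ₂). Assembled from the
calibrated constants these evaluate to 119.9–120.2 kPa across the four
families at homeostasis — in agreement with the reported homeostatic
intramural stress of 120 kPa, which validates both the family-direction
assignment and the density convention.

SMC:  σᵐ = (T₂₂ + T_act)/h_m with h_m = M_Rm/((1−φ_f)ρλ₁λ₂). Two readings of
the T₂₂ term exist. With the *SMC-borne* stress (SMC passive + active; the
default, `numerics.smc_stress_numerator = "smc_only"`) the homeostatic value
is 117.4 kPa ≈ the 120 kPa set point; with the *total* passive membrane
stress it would be 679 kPa, irreconcilable with a 120 kPa normalization. The
default therefore uses the SMC-borne reading; the alternative is one switch
away.

Both ratios are normalized by their *computed* homeostatic values (not the
printed, rounded 120 kPa), which is what makes the production equations
vanish identically at t = 0. An experimental `numerics.stress_stimulus =
"total_hoop"` variant drives production by the total hoop Cauchy stress
instead; it is not the default.

### Homeostatic tone balance

With all printed constants, the circumferential equilibrium at (P_h, r_h)
requires T_act = 0.530 N/m while the tone constants give 0.613 N/m — printed
parameters are rounded, and the basal tone was fit independently of the
mixture assembly. The residual is absorbed into an effective S_basal
(0.862 → 0.746 N/m, −13.4%, warned at runtime and recorded in the result
metadata) so the model starts exactly at equilibrium; `numerics.tone_balance
= "strict"` turns the warning into an error. Likewise the shear ratio is
anchored to the model's own t = 0 inner radius (the printed mass fractions
sum to 0.29999, shifting the assembled thickness by 5×10⁻⁵ relative).

## Numerical scheme

Time marching (default Δt = 0.1 day) per step, first-order operator
splitting:

1. decay every cohort's survival over (t−Δt, t] with μ₂ᵏ evaluated at the
   start-of-step deformation (exact at homeostasis, where ζ = 1 regardless);
2. deposit a provisional cohort for material produced during the step (last
   step's rate, natural configuration refined after the solve) — without it
   the measured mass lags the integral by half a step and the fixed point
   drifts;
3. solve `P r = T₂₂(r) + S(r) λ₂ᵃᶜᵗ f(λ₂ᵃᶜᵗ)` for the mean radius by Newton
   iteration with a central-difference Jacobian (step 10⁻⁷ r_h), tolerance
   10⁻⁹ P_h r_h, falling back to bracketed bisection on [r/2, 2r] if Newton
   leaves a trust region; r_act is frozen during the solve (it relaxes on a
   10-day timescale) while S tracks the shear at the candidate radius;
4. relax r_act exponentially toward the new radius;
5. evaluate the stress stimuli, advance the intermediate pools by their exact
   exponential update (production frozen over the step — unconditionally
   non-negative), set the new cohort's production rate.

Heredity integrals use trapezoidal quadrature over the stored cohort grid
plus a closed-form term for the homeostatic past (all pre-history material
shares one deposition state, so it collapses to a single lumped cohort whose
post-t=0 survival equals that of the τ = 0 cohort). Verified behaviors: the
homeostatic state drifts < 10⁻⁷ in every variable over 300 days; halving Δt
changes 60-day endpoints by < 0.1%; a 20× finer integration reproduces a
perturbed 30-day state to < 10⁻³; the vectorized quadrature matches an
explicit python-loop re-integration to machine precision; pool stepping
matches the closed-form two-pool solution to < 10⁻¹⁰.

Problem sizes: a 300-day run is 3,000 steps over a cohort grid of up to
3,001 points × 5 turning-over constituents, a few seconds on one core. These
durations were chosen because every transient of interest (vasoactive: days;
intermediate pool: 1/(β₂+μ₁) ≈ 3 days; mature collagen: 1/μ₂ = 100 days) is
well resolved and essentially settled by day 300.

## Scenarios and fixtures

Scenarios are piecewise-linear time courses of γ = P/P_h and ε = Q/Q_h,
equal to 1 for t ≤ 0, linearly interpolated between knots and held constant
afterwards; steps, ramps, or CSV-defined courses. The fixture generator
emits a deterministic-by-seed family of synthetic ligation-like flow decays
(ε ∈ [0.3, 1]) and hypertension-like pressure rises (γ ∈ [1, 1.65]) as
stand-ins for measured hemodynamic traces, which are not publicly tabulated.
Passing tests on these synthetic scenarios demonstrates the solver and the
adaptation logic, not agreement with any particular animal experiment.

## Known limitations and expected deviations

- **Pressure-step thickening overshoots the ideal.** After a 50% pressure
  step the ideal adapted wall is 1.5× thicker (restoring σ₂ = P r/h). This
  model converges to ≈ 1.8× with the reference gains: the available tone
  (≤ 4 S_basal ≈ 3 N/m) cannot carry the 2.2 N/m load increment, the lumen
  dilates ~3%, shear drops ~9% for about two weeks, and the strong shear
  gain (K_τw = 52) converts that transient into extra collagen. At any fully
  re-deposited steady state both constituent stress measures return to their
  set points automatically (new cohorts deposit at G_h), so the final
  thickness is selected by the transient, not by a unique attractor —
  published reference trajectories for this protocol report ≈ 1.5, and the
  same mechanism makes our simulated early-phase active stress peak
  (~1040 kPa at day 7) larger than the ~820 kPa reported for that protocol.
- **Small flow reductions under-constrict relative to in-vivo reports.** A
  shear-driven tone cannot quasi-statically constrict past the radius that
  restores shear (−3.45% for a 10% flow drop); reported early responses of
  −4.5% overshoot that point, suggesting additional (e.g. myogenic or
  signaling-dynamics) mechanisms outside this model. The −30% flow response
  (−7.8% vs reported −8.2%) and both dilation responses are reproduced.
- Flow perturbations adapt the lumen to the cube-root law within 1%, but the
  thickness returns toward its baseline rather than the ideal γ ε^{1/3} h_h —
  the permanent elastin pool and the self-neutralizing stress measures leave
  the thickness direction only weakly controlled.
- No residual stress/opening angle, no 3D wall, no elastin damage or
  turnover, no viscoelasticity, no explicit protease (MMP) dynamics, no
  axial growth, no inflammation. Vasoactive signaling is collapsed into the
  algebraic tanh law (optionally first-order-lagged).
- The membrane equilibrium uses the mean radius (P r); the thin-wall Laplace
  form with the inner radius differs by h/2r ≈ 3%, absorbed into the
  homeostatic anchors.
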