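# arterygr

Constrained-mixture growth and remodeling (G&R) of an artery, coupled to a
two-compartment biochemical model of collagen turnover.

Arteries adapt to sustained changes in blood flow and pressure: smooth muscle
tone adjusts the lumen within hours to days, and over weeks to months the wall
itself is rebuilt as collagen and smooth muscle are produced and removed in
the altered mechanical state. `arterygr` simulates this process for a thin-
walled (membrane) cylindrical vessel calibrated to a mouse carotid artery. It
is aimed at vascular mechanobiologists and modelers who want a transparent,
scriptable implementation of stress-mediated collagen turnover kinetics
embedded in a constrained-mixture wall model.

## The model in brief

The wall is a mixture of elastin (permanent), four collagen fiber families
(axial, circumferential, ±47.6°) and circumferential smooth muscle, deforming
together with `F = diag(λ₁, λ₂)`, λ₁ ≡ 1 during G&R. Material deposited at
time τ carries its own natural configuration: a cohort's fiber stretch is
`λ_n(t) = G_h · λ(t)/λ(τ)` with deposition stretch `G_h`. Strain energy and
mass are heredity integrals over deposition times,

    w(t) = ∫ m_R(τ) q(t,τ) Ψ(λ_n(t)) dτ,     q(t,τ) = exp(−∫ μ₂(s) ds),

with exponential fiber energies Ψ and a survival fraction q whose removal
rate μ₂ = K_μ1 + K_μ2 (ζ−1)² grows when a cohort's tension ratio ζ leaves its
deposition value. Membrane stresses follow as T₁₁ = (1/λ₂)∂w/∂λ₁,
T₂₂ = (1/λ₁)∂w/∂λ₂, and the mean radius solves the circumferential
equilibrium `P r = T₂₂ + S λ₂ᵃᶜᵗ f(λ₂ᵃᶜᵗ)` by Newton iteration at every step,
where the active tone `S = 2 S_basal (M_m/M_m(0)) (1 + tanh(−k_ton(τ_w/τ_wh − 1) − ln 3/2))`
is shear-regulated and `f` is a parabolic length–tension factor.

Collagen mass production runs through explicit chemistry: procollagen is
synthesized at a mechano-regulated rate m_p (up with intramural stress above
its set point, down with wall shear above its set point), a fraction β₁ is
secreted into a soluble intermediate microfibril pool,

    dC_I/dt = β₁ m_p /MW − (β₂ + μ₁) C_I,

and cross-links into load-bearing fibers at rate β₂ (removal μ₁ from the
intermediate pool, μ₂ from the mature pool; mean mature-fiber age 1/μ₂ =
100 days). The homeostatic state is an exact fixed point of the discrete
scheme: production balances removal (m_R(0) = μ₂ M_R(0)) and the calibrated
wall is in mechanical equilibrium at P_h = 102 mmHg.

## Worked example

```python
from arterygr import ModelConfig, build_scenario, ideal_adaptation, simulate

config = ModelConfig().replace(K_sigma_c=2.0, K_sigma_m=2.0)
result = simulate(build_scenario("step_flow", 0.7), config, duration=300.0)
f = result.frame
print(f[f.t_day.isin([0, 1, 30, 300])][["t_day", "r_i_mm", "h_um", "tau_ratio"]])
print("ideal lumen ratio:", ideal_adaptation(1.0, 0.7)[0])
```

prints (values from the calibrated mouse carotid wall):

```
     t_day    r_i_mm       h_um  tau_ratio
0      0.0  0.306801  21.198940   1.000000
1      1.0  0.283032  23.439856   0.891581
30    30.0  0.273043  28.277189   0.993050
300  300.0  0.272538  21.867571   0.998589
ideal lumen ratio: 0.8879040017426006
```

Reading: after a 30% flow reduction the lumen constricts acutely by ~8%
(smooth muscle tone responding to low shear, day 1), the wall transiently
thickens as matrix is produced in the constricted state (day 30), and by day
300 the inner radius sits at 0.888 of baseline — the cube-root-law value
(Q/Q_h)^{1/3} that exactly restores wall shear stress — with the shear ratio
back to 1. The `examples/` directory walks through the other capabilities:
hypertensive thickening, early vasoactive responses, the collagen pool
kinetics, and active stress–stretch diagnostics.

A thin CLI mirrors the library:

```
arterygr --scenario step_flow_0.7 --duration 300 --out run.csv
arterygr --scenario step_flow_0.7 --sweep Ksigma=0,2,6,10 --out sweep.csv
arterygr --fixtures 7 --out scenarios/        # synthetic scenario CSVs
```

Each run writes a full-precision time-series CSV and a JSON manifest
(parameters, scenario hash) sufficient to re-run it bit-identically.

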