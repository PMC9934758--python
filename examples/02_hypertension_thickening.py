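"""Wall thickening under a sustained 50% pressure increase.

Raised pressure stretches the wall and drops the shear ratio slightly (the
lumen dilates), both of which drive collagen and smooth muscle production.
The wall thickens over weeks while the lumen is roughly preserved.
"""

from arterygr import ModelConfig, build_scenario, simulate

config = ModelConfig().replace(K_sigma_c=2.0, K_sigma_m=2.0)
result = simulate(build_scenario("step_pressure", 1.5), config, duration=300.0)
f = result.frame

print("50% pressure step, 300 simulated days")
print(f"{'day':>5} {'h/h_h':>7} {'r_i/r_ih':>9} {'sigma2 (kPa)':>12} {'M_m ratio':>9}")
for day in (0, 1, 7, 30, 100, 300):
    row = f[f["t_day"] == day].iloc[0]
    print(f"{day:5.0f} {row.h_um / f.h_um.iloc[0]:7.3f} "
          f"{row.r_i_mm / f.r_i_mm.iloc[0]:9.4f} {row.sigma2_kPa:12.1f} "
          f"{row.M_Rm_ratio:9.3f}")

print("\nThe lumen returns to within ~1% of baseline while the wall thickens")
print("well past the +50% that would exactly restore the hoop stress: with a")
print("permanent (non-remodeling) elastin pool and strongly shear-driven")
print("production, the model settles slightly thicker than the ideal wall.")
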