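"""Active stress-stretch diagnostics as remodeling progresses.

At chosen days of a simulation, the circumferential stretch is swept with
the tone state (magnitude S, active reference radius, muscle mass) frozen,
giving the classic active length-tension curve in Cauchy stress units.
Its peak sits near stretch 2.06 — the argmax of lambda^2 f(lambda), because
muscle thins as 1/lambda — and shifts left once the active reference radius
has adapted inward.
"""

import numpy as np

from arterygr import ModelConfig, active_stress_sweep, build_scenario, simulate

config = ModelConfig().replace(K_sigma_c=3.0, K_sigma_m=3.0)

for label, scenario in (("50% pressure increase", build_scenario("step_pressure", 1.5)),
                        ("30% flow decrease", build_scenario("step_flow", 0.7))):
    result = simulate(scenario, config, duration=300.0)
    print(f"\n{label}:")
    print(f"{'day':>5} {'peak stress (kPa)':>18} {'at stretch':>11}")
    for day in (0.0, 7.0, 14.0, 300.0):
        lam, sig = active_stress_sweep(result, day)
        print(f"{day:5.0f} {sig.max():18.0f} {lam[np.argmax(sig)]:11.2f}")

print("\nUnder pressure the peak location stays ~2.1 (the lumen is preserved,")
print("so the active reference radius barely moves) while the magnitude decays")
print("as shear re-normalizes.  Under reduced flow the vessel and its active")
print("reference radius shrink ~11%, dragging the peak to ~1.8.")
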