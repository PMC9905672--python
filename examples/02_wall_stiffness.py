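"""Passive wall mechanics: pressure ramp -> stress/strain -> stiffness beta.

Simulates a Ca2+-free pressure-diameter ramp for a vessel of known stiffness
using the forward stress-balance model, converts it to circumferential
stress vs strain, and refits the exponential to recover beta.
"""

from vhi import compute_stress_strain, fit_exponential, simulate_passive_mechanics

true_beta = 6.2   # a markedly stiffened arteriole
series = simulate_passive_mechanics(beta=true_beta, id0=90.0, wt0=12.0)

print("P (mmHg)   ID (um)   OD (um)")
for p, idi, odi in zip(series.pressures, series.inner_diameters, series.outer_diameters):
    print(f"{p:7.0f}   {idi:7.1f}   {odi:7.1f}")

ss = compute_stress_strain(series)
fit = fit_exponential(ss)
print(f"\nfitted beta = {fit.beta:.4f} (true {true_beta}), r^2 = {fit.r_squared:.6f}, "
      f"acceptable = {fit.acceptable}")
print("Higher beta means the wall needs more distending stress per unit strain —")
print("a stiffer vessel; fits with r^2 <= 0.85 are flagged unacceptable.")
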