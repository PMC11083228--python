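"""Convert biexponential fit parameters to physiological ones.

The voxelwise fit estimates the biexponential impulse-response
parameters (alpha_plus, alpha_minus, beta_minus); this script maps the
standard starting estimates to the plasma volume fraction vp, the
permeability-surface-area product PS and the plasma flow Fp, and then
to the derived transit-time and extraction parameters.
"""

import ultradce as u

b = u.BiexpParams(alpha_plus=0.2, alpha_minus=0.2, beta_minus=4.0)
p = u.biexp_to_physio(b)
d = u.derive_secondary(p)

print(f"biexponential: alpha+ = {b.alpha_plus}, alpha- = {b.alpha_minus}, "
      f"beta- = {b.beta_minus} /min")
print(f"physiological: Fp = {p.fp:.3f} /min, PS = {p.ps:.3f} /min, "
      f"vp = {p.vp:.3f}")
print(f"derived:       MTTp = {d.mttp:.3f} min, Tc = {d.tc:.3f} min, "
      f"E = {d.e:.3f}, Ktrans = {d.ktrans:.3f} /min")
print()
print("Fp is the plasma flow, PS the leakage rate into the interstitium,")
print("vp the fractional plasma volume; E = PS/(PS+Fp) is the fraction of")
print("inflowing tracer extracted on first pass and Ktrans = E*Fp the")
print("familiar volume transfer constant.")
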