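"""The leaf thermal time constant τ: heat capacity over heat transfer.

τ = φ·LMA·[c_p,w/(LDMC·h) + (c_p,d − c_p,w)/h] with h = a_h·sqrt(u/width).
Small τ = leaves that track environmental changes quickly; large τ =
thermally buffered leaves (thick, wet, wide).
"""

from thermoreg import TauParams, heat_transfer_coefficient, thermal_time_constant, vpd

p = TauParams()  # φ=0.5, c_p,w=4181, c_p,d=2814 J kg⁻¹ K⁻¹, u=1 m s⁻¹, a_h=3.87

for name, lma, ldmc, width_mm in [
    ("thin dry temperate-like leaf", 0.08, 0.55, 20.0),
    ("thick wet alpine-like leaf", 0.12, 0.35, 15.0),
    ("small narrow desert-like leaf", 0.10, 0.45, 6.0),
]:
    h = heat_transfer_coefficient(width_mm / 1000.0, p)
    tau = thermal_time_constant(lma, ldmc, width_mm / 1000.0, p)
    print(f"{name:31s} h = {h:5.1f} W m⁻² K⁻¹   τ = {tau:6.1f} s")

print("\nWetter (lower LDMC) and wider (lower h) leaves respond more slowly.")
print(f"\nGlasshouse check: VPD at 26.3 °C, 30.5 % RH = {vpd(26.3, 30.5):.2f} kPa")
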