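"""Determine an oligomeric state from size-exclusion chromatography.

Fits the log-linear mass calibration to the four classic globular
standards, converts a sample elution volume to a net mass, and divides
by the 16.3 kDa monomer mass to label the oligomeric state.
"""

import lovscreen as lv
from lovscreen.simulate import GeneratorConfig, generate_sec_run

config = GeneratorConfig(seed=3)
standards, sample_volume = generate_sec_run(true_oligomer_state=1.81, config=config)

calibration = lv.fit_calibration(standards)
print("calibration: log10(mass/kDa) = "
      f"{calibration.intercept:.3f} {calibration.slope:+.4f} * V/mL "
      f"(r^2 = {calibration.r_squared:.4f})")
for s in standards:
    print(f"  {s.name:<15s} {s.molecular_mass_kda:7.1f} kDa at {s.elution_volume_ml:.2f} mL")

mass = lv.mass_from_elution(calibration, sample_volume)
estimate = lv.oligomeric_state(mass, monomer_mass_kda=lv.FBFP_MONOMER_KDA)
print(f"\nsample eluted at {sample_volume:.2f} mL -> net mass {mass:.1f} kDa")
print(f"oligomeric state: {estimate.state_value:.2f} ({estimate.state_label})")

# A state value near 1.8 on a 16.3 kDa monomer reads as a dimer, as
# expected for LOV-domain fluorescent proteins.
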