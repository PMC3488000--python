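"""Quantum yield and holoprotein fraction of a bright mutant.

Generates a concentration series for a protein with true quantum yield
0.30 and holoprotein fraction 0.49 (the F37S-like case), plus the FMN
reference series (known QY 0.27), and recovers both quantities.
"""

import lovscreen as lv
from lovscreen.simulate import GeneratorConfig, generate_photophysics_series

config = GeneratorConfig(seed=7)
samples, fmn_standard = generate_photophysics_series(
    true_qy=0.30, true_f_holo=0.49, config=config
)

qy = lv.quantum_yield(samples, fmn_standard)
print(f"quantum yield: {qy.value:.3f} +/- {qy.sd:.3f}  (true 0.300)")

holo = lv.holo_fraction_series(samples)
print(f"holoprotein fraction: {holo.f_holo:.3f} +/- {holo.sd:.3f}  (true 0.490)")

wt_qy = lv.Measurement(0.17, 0.0)  # literature wild-type quantum yield
fold = lv.fold_with_error(lv.Measurement(qy.value, qy.sd), wt_qy)
print(f"fold enhancement over wild type: {lv.round_sig(fold.value)} "
      f"+/- {fold.sd:.2f}")

# The quantum yield is the ratio of integrated-emission-per-absorbance
# between sample and FMN standard, scaled by the standard's known QY;
# the holoprotein fraction is the Beer-Lambert 450 nm concentration
# over the Bradford total-protein concentration.
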