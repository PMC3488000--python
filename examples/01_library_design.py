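"""Design an NNK saturation library and size the screening effort.

Builds the F37X mutagenic primer, enumerates the NNK codon space, and
answers the two screening-statistics questions: how much of the library
do 180 picked colonies cover, and how many colonies would guarantee
(with 95% probability) that *every* variant was seen at least once?
"""

import lovscreen as lv

primer = lv.build_mutagenic_primer("CGTCAACCCGGCC", "NNK", "GAGCGCCTGACC")
print(f"F37X primer: {primer.sequence} (degenerate codon at offset {primer.degenerate_start})")

codons = lv.expand_degenerate_codon("NNK")
dist = lv.amino_acid_distribution("NNK", include_stop=True)
print(f"NNK expands to {len(codons)} codons encoding {len(dist) - 1} residues "
      f"+ stop (P = {dist['*']:.4f})")

uniform = [1 / 32] * 32
n = 180
print(f"\n{n} colonies = {lv.oversampling_factor(n, 'NNK'):.3f}-fold oversampling")
print(f"Expected fraction of variants seen: "
      f"{lv.expected_coverage_fraction(n, uniform):.1%}")
print(f"Probability every variant was seen: "
      f"{lv.coverage_probability(n, uniform).p_complete:.1%}")
print(f"Colonies for 95% complete coverage: {lv.required_clones(uniform, 0.95)}")

# The expected-fraction numbers drive the classic -V*ln(1-F) rule of
# thumb (96 clones -> 95% of NNK variants on average); guaranteeing that
# *all 32* codons appear is a stricter, coupon-collector question.
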