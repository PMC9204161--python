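"""Calibrate a soft-randomized library and inspect its expected composition.

Soft randomization synthesizes each evolvable codon from doped nucleotide
mixtures that favor the template base.  Here we solve the per-base retention
fraction that yields a 50% amino-acid mutation rate per position, print the
expected residue distribution the library should show before selection, and
emit the degenerate primer specifications a synthesis vendor would need.
"""

import twopan as tp

# retention fraction p: template base kept with p, others (1-p)/3 each
p_codon = tp.solve_base_retention(0.5, "TAT", level="codon")
p_aa = tp.solve_base_retention(0.5, "TAT", level="amino_acid")
print(f"retention for 50% codon-level mutation:      p = {p_codon:.4f}")
print(f"retention for 50% amino-acid-level mutation: p = {p_aa:.4f}")
print("(the amino-acid level needs heavier doping: synonymous codons")
print(" silently restore the template residue)\n")

design = tp.default_design(rate=0.5, level="amino_acid")
profile = tp.expected_library_profile(design)
print("expected naive-library proportions of the template residues:")
for pos, aa in zip(design.position_names, design.template_residues):
    print(f"  {pos:>4} {aa}: {100 * profile.at[pos, aa]:5.1f}%")
print("(close to 50% plus the share reclaimed from discarded stop codons)\n")

print("degenerate primer specification:")
print(tp.emit_degenerate_primers(design))
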