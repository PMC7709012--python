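"""Physico-chemical behaviour of two published silicification peptides.

KEKPVKPPKKHPPP is an in-vitro silica-precipitating signature; silica
deposition tracks the density of positively charged residues, so replacing
every lysine with alanine should collapse that density.  The 23-mer
KPPIYKPPVYTPPVYKPPVEKPP is a repeat unit reported to occur eight times in
a moderate-accumulator extensin-like protein.
"""

from siliscan import alanine_scan, find_tandem_repeats, isoelectric_point, positive_charge_density

signature = "KEKPVKPPKKHPPP"
density = positive_charge_density(signature)
mutant, before, after = alanine_scan(signature, "K")
print(f"signature {signature}")
print(f"  positive-charge density: {density:.4f}  ({round(density * len(signature))}"
      f"/{len(signature)} residues are K/R/H)")
print(f"  K->A scan: {mutant}  density {before:.4f} -> {after:.4f}")
print(f"  pI: {isoelectric_point(signature):.2f} (strongly basic, as expected "
      "for a silica-precipitating peptide)")

unit = "KPPIYKPPVYTPPVYKPPVEKPP"
blocks = find_tandem_repeats(unit * 8)
block = blocks[0]
print(f"tandem array of the printed unit: {block.copies} copies of "
      f"{block.unit} spanning {block.start}-{block.end} "
      f"(identity {block.identity:.2f})")
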