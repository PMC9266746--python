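"""Neutral masses, negative-mode m/z and CID fragment ladders.

Masses are derived from elemental formulas via a single atomic-mass table.
The 2',3'-cyclic phosphate of an endonucleolytic product is one water
lighter than a linear 3'-phosphate; negative-mode ions are deprotonated.
"""

from rnasespec import fragment_ladder, mz, neutral_mass, parse_sequence

prod = parse_sequence("UUGAGA", terminus3="cyclic_phosphate")
M = neutral_mass(prod)
print(f"product      : {prod} (5'-OH / 3'->p)")
print(f"neutral mass : {M:.4f} Da (monoisotopic)")
for z in (-1, -2, -3):
    print(f"  m/z at z={z:>2}: {mz(M, z):.4f}")
linear = parse_sequence("UUGAGA", terminus3="phosphate")
print(f"cyclic vs linear 3'-phosphate: {neutral_mass(linear) - M:.4f} Da "
      "(one water)")

print("\nc/y/w/a-B fragment ladder (sequencing ions):")
for ion in sorted(fragment_ladder(prod), key=lambda i: (i.series, i.index)):
    lost = f"  -{ion.lost_base}" if ion.lost_base else ""
    print(f"  {ion.series:>3}{ion.index}  {ion.neutral_mass:10.4f} Da  "
          f"{ion.description}{lost}")
# Complementary c_i/y_(n-i) pairs sum to the precursor mass + H2O: both
# fragments keep the full cut-site chemistry, which is how ladder matching
# confirms a product's sequence.
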