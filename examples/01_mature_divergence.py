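"""Compare the two published mature miRNAs.

Slides miR1448 against miR482.2 over all ungapped offsets and reports the
identity-maximising comparison.  The two matures share 15 of 19 overlapping
sites; all four differences are transversions — the signature substitution
pattern of the duplicate.
"""

from pcevol import best_offset_identity
from pcevol.synthetic import MIR1448, MIR482_2

cmp = best_offset_identity(MIR482_2, MIR1448)
print(f"miR482.2  5'{MIR482_2}3'")
print(f"miR1448   5'{MIR1448}3'")
print(f"best offset          : {cmp.offset}")
print(f"identical sites      : {cmp.identities} of {cmp.compared_sites} compared")
print(f"transitions          : {cmp.transitions}")
print(f"transversions        : {cmp.transversions}")
for pos, a, b in cmp.diff_positions:
    print(f"  difference at miR482.2 position {pos + 1}: {a} -> {b}")
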