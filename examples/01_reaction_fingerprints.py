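"""Fingerprint a single reaction three ways.

Parses an esterification reaction SMILES and prints the length and
number of set bits of each binary fingerprint. The structural scheme
encodes what is present on each side (substrate half ∥ product half);
the differential scheme marks hashed bins whose substructure counts
differ between sides; the difference (DRFP-style) scheme marks
substructures appearing on exactly one side.
"""

from kcatpred import (
    difference_fingerprint,
    differential_fingerprint,
    parse_reaction,
    structural_fingerprint,
)

rxn = parse_reaction("CC(=O)O.OCC>>CC(=O)OCC.O")  # acetic acid + ethanol
print(f"substrates: {rxn.substrates}   products: {rxn.products}")

for name, fp in [
    ("structural ", structural_fingerprint(rxn)),
    ("differential", differential_fingerprint(rxn)),
    ("difference  ", difference_fingerprint(rxn)),
]:
    print(f"{name}: length {len(fp)}, {int(fp.sum())} bits set")

# identity reactions carry no chemical change, so both difference-type
# fingerprints are exactly zero
ident = parse_reaction("C>>C")
print("identity difference bits:", int(difference_fingerprint(ident).sum()))
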