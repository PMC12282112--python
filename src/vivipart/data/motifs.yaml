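# Diagnostic motif catalog.
#
# Each motif is an ordered list of residue-class blocks with bounded spacers
# between consecutive blocks (number of residues strictly between them).
# A class is a string of allowed residues; "x" matches any residue.
# Spacer bounds bracket the FaVvV1 exemplars (e.g. the serine-protease triad
# His357/Asp400/Ser475 gives gaps of 42 and 74) and can be edited freely.

PCPro:
  description: >
    Papain-like cysteine protease: GXCY ... H/R ... [VILM]G|G, with the
    cleavage site between the two glycines adjacent to the catalytic dyad.
  blocks:
    - [G, x, C, Y]
    - [HR]
    - [VILM, G, G]
  spacers:
    - [10, 60]
    - [10, 120]

Mtr:
  description: >
    Canonical methyltransferase of Martellivirales-like replicases: cap
    transfer (H) and S-adenosylmethionine binding (DXG, DXXR) motifs.
  blocks:
    - [H]
    - [D, x, G]
    - [D, x, x, R]
  spacers:
    - [40, 200]
    - [5, 150]

CSPro:
  description: >
    Chymotrypsin-type serine protease catalytic triad His/Asp/Ser.
  blocks:
    - [H]
    - [D]
    - [S]
  spacers:
    - [20, 80]
    - [40, 120]
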