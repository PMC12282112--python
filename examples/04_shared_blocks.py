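"""Detect the recombination/duplication blocks shared between segments.

On the simulated first virus, seed-and-extend finds the planted identical
5' 800-nt and 3' 263-nt blocks at exact length; the 101-nt 90% block is
measured by anchored terminal identity, since near-identical blocks are a
positional comparison, not an exact-match one.
"""

from vivipart import (
    SequenceRecord,
    SimulationConfig,
    find_shared_blocks,
    longest_common_prefix,
    longest_common_suffix,
    reverse_complement,
    simulate,
    terminal_identity,
)

records, truth = simulate(SimulationConfig(seed=7))
plus = {
    r.id: (reverse_complement(r.residues) if truth.orientation[r.id] == "-" else r.residues)
    for r in records
}

b5, b263, b101 = truth.planted_blocks
pair = [
    SequenceRecord(b5["seg_a"], plus[b5["seg_a"]], moltype="nucleotide"),
    SequenceRecord(b5["seg_b"], plus[b5["seg_b"]], moltype="nucleotide"),
]
print(f"identical 5' prefix ({b5['seg_a']}/{b5['seg_b']}): "
      f"{longest_common_prefix(*pair)} nt")
print(f"identical 3' suffix ({b263['seg_a']}/{b263['seg_b']}): "
      f"{longest_common_suffix(plus[b263['seg_a']], plus[b263['seg_b']])} nt")
ung, gapped = terminal_identity(plus[b101["seg_a"]], plus[b101["seg_b"]], "3'", 101)
print(f"3' 101-nt block identity ({b101['seg_a']}/{b101['seg_b']}): "
      f"{ung * 100:.1f}% ungapped ({gapped * 100:.1f}% gapped)")

blocks = find_shared_blocks(pair)
for b in blocks:
    print(f"  detected {b.location:12s} {b.length:4d} nt at "
          f"identity {b.identity:.3f}")
# 800/263 nt come out exactly; 90.1% = 91 matching positions of 101 —
# evidence that one segment's ends were rebuilt from the other two.
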