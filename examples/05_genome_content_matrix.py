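"""Cluster segment proteins across viruses and call duplicated segments.

Longest-ORF proteins of every assigned segment are greedily clustered
(30% identity, 50% bidirectional coverage); the virus-by-cluster copy
matrix exposes the conserved core content, and any cell >= 2 is a
duplicated segment.
"""

from vivipart import (
    SequenceRecord,
    SimulationConfig,
    assign_genomes,
    content_matrix,
    detect_duplications,
    find_orfs,
    greedy_cluster,
    reverse_complement,
    simulate,
)

records, truth = simulate(SimulationConfig(seed=7))
decisions, bundles, strands = assign_genomes(records, truth.coverage, truth.anchors)
plus = {
    r.id: (reverse_complement(r.residues) if strands[r.id] == "-" else r.residues)
    for r in records
}

proteins = []
for b in bundles:
    for m in b.members:
        orfs = find_orfs(plus[m], min_aa=50)
        proteins.append(SequenceRecord(m, orfs[0].protein, moltype="protein"))

ca = greedy_cluster(proteins)
matrix = content_matrix(bundles, ca)
print("genome content (viruses x homolog clusters):")
print(matrix.to_string())
print()
for e in detect_duplications(matrix, ca, bundles):
    print(f"duplicated segment: {e.virus_id} {e.cluster_id} "
          f"x{e.count} ({', '.join(e.members)})")
# Each row sums to that virus's segment count; shared columns are the
# conserved core cassettes, single-virus columns are orphan segments, and
# cells of 2+ are within-genome duplications.
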