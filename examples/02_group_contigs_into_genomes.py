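"""Assign orphan contigs to virus genomes via conserved 5' termini.

Orients every contig to its poly(A) strand, bundles the RdRP-bearing
anchor contigs into one bundle per virus, filters on k-mer coverage, and
assigns each dark contig to the bundle whose 100-nt terminal consensus it
matches at >= 70% identity with a 5-point ambiguity margin.
"""

from sklearn.metrics import adjusted_rand_score

from vivipart import SimulationConfig, assign_genomes, simulate

records, truth = simulate(SimulationConfig(seed=7))
decisions, bundles, strands = assign_genomes(records, truth.coverage, truth.anchors)

print(f"bundles found: {len(bundles)} (true viruses: {len(truth.virus_motifs)})")
for d in decisions[:5]:
    print(f"  {d.contig_id:14s} -> {d.assigned:11s} "
          f"best={d.best_identity:.2f} second={d.second_best_identity:.2f} "
          f"[{d.rationale}]")

pred = {m: b.virus_id for b in bundles for m in b.anchors}
for d in decisions:
    pred[d.contig_id] = d.assigned if d.rationale == "assigned" else "unassigned"
ids = sorted(pred)
ari = adjusted_rand_score([truth.membership[i] for i in ids], [pred[i] for i in ids])
print(f"adjusted Rand index vs truth: {ari:.3f}")
# ARI 1.0 means every segment went to the right genome and every decoy was
# left unassigned; the best/second identities show why the margin rule is
# safe (same-virus termini score ~0.85+, unrelated ones ~0.45).
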