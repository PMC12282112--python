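"""End-to-end recovery scoring against simulator ground truth.

Runs the full pipeline on one simulated virus set — orientation, terminal
bundling, orphan assignment, longest-ORF annotation, homolog clustering,
duplication calling, shared-block detection — and scores every planted
quantity.  This is both the package's benchmark and the honest statement of
what it can recover under the stated study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.metrics import adjusted_rand_score

from .annotate import find_orfs
from .core_io import SequenceRecord, reverse_complement
from .grouping import assign_genomes
from .homology_clusters import content_matrix, detect_duplications, greedy_cluster
from .align import ScoringScheme, star_msa
from .phylo_lite import is_split, neighbor_joining, p_distance_matrix
from .shared_regions import (
    find_shared_blocks,
    longest_common_prefix,
    longest_common_suffix,
    terminal_identity,
)
from .synthetic_data import GroundTruth, SimulationConfig, simulate
from .terminus import conserved_terminal_length, max_tandem_repeat

__all__ = ["RecoveryReport", "evaluate_recovery"]


@dataclass
class RecoveryReport:
    seed: int
    n_contigs: int
    membership_ari: float
    cluster_ari: float
    duplications_exact: bool
    duplicate_clades_ok: bool  # pairs form NJ-tree clades (unrooted)
    n_duplication_events: int
    orf_recovery: float  # fraction of planted ORFs recovered verbatim
    planted_prefix_len: int  # recomputed longest common 5' prefix
    planted_suffix_len: int  # recomputed longest common 3' suffix
    planted_block_identity: float  # recomputed 3' near-identical block
    exact_blocks_detected: bool  # identity-1.0 blocks found at exact length
    conserved_terminal_length: int
    terminal_repeat_copies: int


def evaluate_recovery(cfg: SimulationConfig) -> RecoveryReport:
    records, truth = simulate(cfg)
    decisions, bundles, strands = assign_genomes(
        records, truth.coverage, truth.anchors
    )
    plus = {
        r.id: (
            reverse_complement(r.residues)
            if strands[r.id] == "-"
            else r.residues
        )
        for r in records
    }

    # contig-to-genome membership
    pred = {m: b.virus_id for b in bundles for m in b.anchors}
    for d in decisions:
        pred[d.contig_id] = d.assigned if d.rationale == "assigned" else "unassigned"
    ids = sorted(pred)
    membership_ari = adjusted_rand_score(
        [truth.membership[i] for i in ids], [pred[i] for i in ids]
    )

    # planted ORFs, verbatim
    recovered = 0
    proteins = []
    member_ids = {m for b in bundles for m in b.members}
    for cid, o in truth.planted_orfs.items():
        orfs = find_orfs(plus[cid], min_aa=cfg.orf_min_aa)
        spans = {(x.nt_span.start, x.nt_span.end, x.frame) for x in orfs}
        if (o["start"], o["end"], o["frame"]) in spans:
            recovered += 1
    orf_recovery = recovered / max(len(truth.planted_orfs), 1)
    for m in sorted(member_ids):
        orfs = find_orfs(plus[m], min_aa=cfg.orf_min_aa)
        if orfs:
            proteins.append(
                SequenceRecord(id=m, residues=orfs[0].protein, moltype="protein")
            )

    # homolog clusters and duplications
    ca = greedy_cluster(proteins)
    cluster_ari = adjusted_rand_score(
        [truth.segment_class[p.id] for p in proteins],
        [ca.assignment[p.id] for p in proteins],
    )
    matrix = content_matrix(bundles, ca)
    events = detect_duplications(matrix, ca, bundles)
    got = {e.members for e in events}
    expected = set()
    for (virus, klass), _count in truth.duplication_events().items():
        expected.add(
            tuple(sorted(
                c for c, v in truth.membership.items()
                if v == virus and truth.segment_class.get(c) == klass
            ))
        )
    duplications_exact = got == expected

    # every duplicate pair must group as a clade of its cluster's NJ tree
    # (unrooted reading: clade under some rooting outside the pair)
    duplicate_clades_ok = True
    protein_by_id = {p.id: p for p in proteins}
    for e in events:
        members = sorted(ca.clusters()[e.cluster_id])
        if len(members) < 3:
            continue
        msa = star_msa(
            [protein_by_id[m] for m in members], ScoringScheme.protein()
        )
        tree = neighbor_joining(p_distance_matrix(msa))
        duplicate_clades_ok &= is_split(tree, set(e.members))

    # planted shared blocks
    blocks_by_pair = {}
    prefix_len = suffix_len = 0
    block_identity = 0.0
    exact_found = True
    for b in truth.planted_blocks:
        sa, sb = plus[b["seg_a"]], plus[b["seg_b"]]
        if b["identity"] == 1.0:
            if b["end"] == "5'":
                prefix_len = longest_common_prefix(sa, sb)
            else:
                suffix_len = longest_common_suffix(sa, sb)
            pair = [
                SequenceRecord(b["seg_a"], sa, moltype="nucleotide"),
                SequenceRecord(b["seg_b"], sb, moltype="nucleotide"),
            ]
            found = find_shared_blocks(pair)
            exact_found &= any(
                x.length == b["length"] and x.identity == 1.0
                and x.location.startswith(b["end"][0])
                for x in found
            )
        else:
            ung, _ = terminal_identity(sa, sb, b["end"], b["length"])
            block_identity = ung

    # terminal conservation of the first virus
    first_virus = sorted(truth.virus_motifs)[0]
    members = [
        SequenceRecord(c, plus[c], moltype="nucleotide")
        for c in sorted(truth.membership)
        if truth.membership[c] == first_virus
    ]
    cons_len = conserved_terminal_length(members[:6], max_length=150)

    # tandem copy number as read off the terminal alignment: the maximum
    # observed among the virus's segments (terminal point mutations shorten
    # individual segments' exact tandems, never lengthen them)
    repeat_copies = 0
    for m in members:
        hit = max_tandem_repeat(
            m.residues[: cfg.terminal_motif_length], cfg.repeat_unit
        )
        if hit is not None:
            repeat_copies = max(repeat_copies, hit.copies)

    return RecoveryReport(
        seed=cfg.seed,
        n_contigs=len(records),
        membership_ari=float(membership_ari),
        cluster_ari=float(cluster_ari),
        duplications_exact=duplications_exact,
        duplicate_clades_ok=duplicate_clades_ok,
        n_duplication_events=len(events),
        orf_recovery=orf_recovery,
        planted_prefix_len=prefix_len,
        planted_suffix_len=suffix_len,
        planted_block_identity=block_identity,
        exact_blocks_detected=exact_found,
        conserved_terminal_length=cons_len,
        terminal_repeat_copies=repeat_copies,
    )
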