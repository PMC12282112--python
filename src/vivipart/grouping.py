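"""Assignment of assembled contigs to multipartite virus genomes.

The procedure mirrors how segmented-virus genomes are completed from a
metatranscriptome: orient every contig to the poly(A)-bearing plus strand,
filter on assembler k-mer coverage against the anchor segments, cluster the
anchor (marker-bearing, e.g. RdRP) contigs into one bundle per virus by 5'
terminal-window similarity, and then assign orphan ("dark") contigs to the
bundle whose terminal consensus they match — with an ambiguity margin so
related co-infecting viruses never silently absorb each other's segments.

The coverage filter is advisory: it partitions, it never deletes, so every
decision stays auditable.  Contigs are processed in lexicographic id order
and repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import global_align, percent_identity
from .annotate import find_orfs
from .core_io import SequenceRecord, get_logger, reverse_complement
from .terminus import (
    TerminalProfile,
    build_terminal_profile,
    max_tandem_repeat,
    terminal_window,
)

__all__ = [
    "VirusBundle",
    "AssignmentDecision",
    "orient",
    "coverage_filter",
    "seed_bundles",
    "assign_orphans",
    "assign_genomes",
]

logger = get_logger(__name__)


@dataclass
class VirusBundle:
    virus_id: str
    members: list[str]
    profile: TerminalProfile
    anchors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("bundle without members")


@dataclass
class AssignmentDecision:
    contig_id: str
    assigned: str  # virus_id, "unassigned" or "decoy"
    best_identity: float
    second_best_identity: float
    coverage_pass: bool
    rationale: str  # assigned | below_threshold | ambiguous | coverage_fail

    def __post_init__(self) -> None:
        if self.best_identity < self.second_best_identity:
            raise ValueError("best identity below second best")
        if self.assigned not in ("unassigned", "decoy") and self.rationale != "assigned":
            raise ValueError("assigned decision must carry rationale 'assigned'")


def _polyA_run(seq: str) -> int:
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    return n - i


def _longest_orf_aa(seq: str) -> int:
    orfs = find_orfs(seq, min_aa=1)
    return len(orfs[0].protein) if orfs else 0


def orient(
    contig: SequenceRecord, min_run: int = 8
) -> tuple[SequenceRecord, str]:
    """Orient a contig to its plus (poly(A)-bearing) strand.

    The strand whose 3' end carries a poly(A) run of at least ``min_run``
    wins; if neither or both qualify, the strand with the longer longest
    ORF wins; remaining ties keep the input strand, flagged "ambiguous".
    Idempotent: an oriented contig re-orients to itself.
    """
    fwd = contig.residues
    rev = reverse_complement(fwd)
    run_f, run_r = _polyA_run(fwd), _polyA_run(rev)
    if (run_f >= min_run) != (run_r >= min_run):
        if run_f >= min_run:
            return contig, "+"
        return (
            SequenceRecord(id=contig.id, residues=rev,
                           description=contig.description,
                           moltype="nucleotide"),
            "-",
        )
    orf_f, orf_r = _longest_orf_aa(fwd), _longest_orf_aa(rev)
    if orf_f > orf_r:
        return contig, "+"
    if orf_r > orf_f:
        return (
            SequenceRecord(id=contig.id, residues=rev,
                           description=contig.description,
                           moltype="nucleotide"),
            "-",
        )
    return contig, "ambiguous"


def coverage_filter(
    contigs: list[SequenceRecord],
    coverage: dict[str, float],
    anchor_ids: list[str],
    min_ratio: float = 0.1,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition contigs by depth relative to the anchor members.

    A contig passes iff its depth is at least ``min_ratio`` times the
    median anchor depth.  Contigs without a coverage entry are warned about
    and fail.  Nothing is discarded: both partitions are returned.
    """
    anchor_depths = sorted(
        coverage[a] for a in anchor_ids if a in coverage
    )
    if not anchor_depths:
        raise ValueError("no anchor contig has a coverage entry")
    m = len(anchor_depths)
    median = (
        anchor_depths[m // 2]
        if m % 2
        else (anchor_depths[m // 2 - 1] + anchor_depths[m // 2]) / 2
    )
    cutoff = min_ratio * median
    logger.info(
        "coverage filter: anchor median %.1f, min_ratio %.2f, cutoff %.1f",
        median, min_ratio, cutoff,
    )
    passed: list[SequenceRecord] = []
    failed: list[SequenceRecord] = []
    for contig in sorted(contigs, key=lambda r: r.id):
        depth = coverage.get(contig.id)
        if depth is None:
            logger.warning("contig %s has no coverage entry; failing it",
                           contig.id)
            failed.append(contig)
        elif depth >= cutoff:
            passed.append(contig)
        else:
            failed.append(contig)
    return passed, failed


def _window_record(rec: SequenceRecord, window: int) -> SequenceRecord:
    return SequenceRecord(
        id=rec.id, residues=terminal_window(rec.residues, window, "5'"),
        moltype="nucleotide",
    )


def _window_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    return percent_identity(global_align(a, b), "all_columns")


def _singleton_profile(member: SequenceRecord, window: int,
                       virus_id: str, repeat_unit: str) -> TerminalProfile:
    w = terminal_window(member.residues, window, "5'")
    return TerminalProfile(
        virus_id=virus_id,
        window_length=len(w),
        consensus=w,
        per_column_conservation=[1.0] * len(w),
        repeat={member.id: max_tandem_repeat(w, repeat_unit)},
    )


def seed_bundles(
    anchored: list[SequenceRecord],
    window: int = 100,
    link_threshold: float = 0.70,
    repeat_unit: str = "CAAAA",
) -> list[VirusBundle]:
    """Single-linkage clustering of anchor contigs on 5'-window identity.

    Each cluster becomes one virus bundle with a terminal profile.  The
    0.70-over-100-nt default separates unrelated random termini (alignment
    identity well below 0.5) from same-virus termini at a few percent
    divergence.
    """
    if not anchored:
        raise ValueError("seed_bundles requires >= 1 anchored contig")
    anchored = sorted(anchored, key=lambda r: r.id)
    windows = [_window_record(r, window) for r in anchored]
    parent = list(range(len(anchored)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(anchored)):
        for j in range(i + 1, len(anchored)):
            if _window_identity(windows[i], windows[j]) >= link_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(anchored)):
        groups.setdefault(find(i), []).append(i)

    bundles: list[VirusBundle] = []
    for k, root in enumerate(sorted(groups)):
        idxs = groups[root]
        members = [anchored[i] for i in idxs]
        virus_id = f"genome_{k + 1:02d}"
        if len(members) >= 2:
            profile = build_terminal_profile(
                members, window=window, virus_id=virus_id,
                repeat_unit=repeat_unit,
            )
        else:
            profile = _singleton_profile(members[0], window, virus_id,
                                         repeat_unit)
        bundles.append(
            VirusBundle(
                virus_id=virus_id,
                members=[m.id for m in members],
                profile=profile,
                anchors=[m.id for m in members],
            )
        )
    return bundles


def assign_orphans(
    orphans: list[SequenceRecord],
    bundles: list[VirusBundle],
    window: int = 100,
    assign_threshold: float = 0.70,
    margin: float = 0.05,
    coverage_pass: dict[str, bool] | None = None,
) -> list[AssignmentDecision]:
    """Assign each orphan to the bundle whose terminal consensus it matches.

    Assignment requires best identity >= ``assign_threshold`` and a lead of
    at least ``margin`` over the runner-up (vacuous with a single bundle);
    the margin guards against silent misassignment between related viruses
    co-occurring in one sample.  A contig failing the coverage filter is
    never assigned.
    """
    if not bundles:
        raise ValueError("assign_orphans requires bundles")
    consensi = [
        SequenceRecord(
            id=b.virus_id,
            residues=b.profile.consensus.replace("-", ""),
            moltype="nucleotide",
        )
        for b in bundles
    ]
    decisions: list[AssignmentDecision] = []
    for orphan in sorted(orphans, key=lambda r: r.id):
        w = _window_record(orphan, window)
        idents = sorted(
            ((_window_identity(w, c), b.virus_id) for c, b in zip(consensi, bundles)),
            key=lambda t: (-t[0], t[1]),
        )
        best, best_virus = idents[0]
        second = idents[1][0] if len(idents) > 1 else 0.0
        cov_ok = True if coverage_pass is None else coverage_pass.get(orphan.id, False)
        if not cov_ok:
            decisions.append(
                AssignmentDecision(orphan.id, "unassigned", best, second,
                                   False, "coverage_fail")
            )
        elif best < assign_threshold:
            decisions.append(
                AssignmentDecision(orphan.id, "unassigned", best, second,
                                   True, "below_threshold")
            )
        elif len(idents) > 1 and best - second < margin:
            decisions.append(
                AssignmentDecision(orphan.id, "unassigned", best, second,
                                   True, "ambiguous")
            )
        else:
            decisions.append(
                AssignmentDecision(orphan.id, best_virus, best, second,
                                   True, "assigned")
            )
    return decisions


def assign_genomes(
    records: list[SequenceRecord],
    coverage: dict[str, float],
    anchor_ids: list[str],
    window: int = 100,
    link_threshold: float = 0.70,
    assign_threshold: float = 0.70,
    margin: float = 0.05,
    min_ratio: float = 0.1,
    min_polyA_run: int = 8,
) -> tuple[list[AssignmentDecision], list[VirusBundle], dict[str, str]]:
    """End-to-end grouping: orient, bundle anchors, filter, assign orphans.

    Returns per-orphan decisions, the bundles (with assigned orphans folded
    into their member lists), and the orientation flag per contig.
    """
    logger.info(
        "grouping: window=%d link=%.2f assign=%.2f margin=%.2f min_ratio=%.2f",
        window, link_threshold, assign_threshold, margin, min_ratio,
    )
    oriented: dict[str, SequenceRecord] = {}
    strands: dict[str, str] = {}
    for rec in sorted(records, key=lambda r: r.id):
        o, flag = orient(rec, min_run=min_polyA_run)
        oriented[rec.id] = o
        strands[rec.id] = flag
    anchors = [oriented[a] for a in sorted(anchor_ids)]
    orphans = [oriented[r.id] for r in records if r.id not in set(anchor_ids)]
    bundles = seed_bundles(anchors, window=window, link_threshold=link_threshold)
    passed, failed = coverage_filter(orphans, coverage, list(anchor_ids),
                                     min_ratio=min_ratio)
    cov_ok = {r.id: True for r in passed}
    cov_ok.update({r.id: False for r in failed})
    decisions = assign_orphans(
        orphans, bundles, window=window, assign_threshold=assign_threshold,
        margin=margin, coverage_pass=cov_ok,
    )
    by_virus = {b.virus_id: b for b in bundles}
    for d in decisions:
        if d.rationale == "assigned":
            by_virus[d.assigned].members.append(d.contig_id)
    for b in bundles:
        b.members.sort()
    return decisions, bundles, strands
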