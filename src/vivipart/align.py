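"""Pairwise and star-MSA alignment primitives.

Terminal-motif comparison, homolog clustering and shared-region identity all
rest on the same affine-gap global alignment.  The dynamic program itself is
delegated to :class:`Bio.Align.PairwiseAligner` (optimal affine-gap global
alignment, deterministic first traceback); this module fixes the scoring
conventions and adds identity computation, the star MSA used for terminal
profiles, and majority-rule consensus.

Gap convention: a gap of length ``L`` scores ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import Interval, SequenceRecord

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "Msa",
    "global_align",
    "percent_identity",
    "star_msa",
    "consensus",
]

#: Default nucleotide scoring: favors contiguous terminal matches over
#: scattered identity (high gap-open, cheap extension).
DEFAULT_NUC = dict(match=1, mismatch=-1, gap_open=-4, gap_extend=-1)


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    #: named substitution table (e.g. "BLOSUM62"); used instead of
    #: match/mismatch for protein alignments
    protein_matrix: str | None = None

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.match <= self.mismatch:
            raise ValueError("require match > mismatch")

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        return cls(**DEFAULT_NUC)

    @classmethod
    def protein(cls) -> "ScoringScheme":
        # BLOSUM62 with BLAST-style affine gaps
        return cls(match=1, mismatch=-1, gap_open=-11, gap_extend=-1,
                   protein_matrix="BLOSUM62")


@dataclass
class PairwiseAlignment:
    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    identity: float
    query_span: Interval
    target_span: Interval

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("gapped rows differ in length")
        for cq, ct in zip(self.aligned_query, self.aligned_target):
            if cq == "-" and ct == "-":
                raise ValueError("column gapped in both rows")


def _make_aligner(scoring: ScoringScheme, moltype: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if moltype == "protein" and scoring.protein_matrix:
        aligner.substitution_matrix = substitution_matrices.load(
            scoring.protein_matrix
        )
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _default_scoring(moltype: str) -> ScoringScheme:
    return ScoringScheme.protein() if moltype == "protein" else ScoringScheme.nucleotide()


def global_align(
    a: SequenceRecord, b: SequenceRecord, scoring: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two same-moltype records."""
    if a.moltype != b.moltype:
        raise ValueError(
            f"cannot align {a.moltype} {a.id!r} against {b.moltype} {b.id!r}"
        )
    if scoring is None:
        scoring = _default_scoring(a.moltype)
    aligner = _make_aligner(scoring, a.moltype)
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    pw = PairwiseAlignment(
        query_id=a.id,
        target_id=b.id,
        aligned_query=row_a,
        aligned_target=row_b,
        score=float(aln.score),
        identity=matches / len(row_a),
        query_span=Interval(0, len(a.residues)),
        target_span=Interval(0, len(b.residues)),
    )
    return pw


def _end_gap_bounds(row_a: str, row_b: str) -> tuple[int, int]:
    """Column range [lo, hi) after dropping terminal columns gapped in
    either row."""
    n = len(row_a)
    lo = 0
    while lo < n and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    return lo, hi


def percent_identity(alignment: PairwiseAlignment, mode: str = "all_columns") -> float:
    """Fraction of matching columns.

    ``exclude_end_gaps`` drops leading/trailing columns that are gapped in
    either row before counting, so segments truncated by assembly are not
    penalized.
    """
    row_a, row_b = alignment.aligned_query, alignment.aligned_target
    if mode == "all_columns":
        lo, hi = 0, len(row_a)
    elif mode == "exclude_end_gaps":
        lo, hi = _end_gap_bounds(row_a, row_b)
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    if hi <= lo:
        raise ValueError("no counted columns in alignment")
    matches = sum(
        1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x == y and x != "-"
    )
    return matches / (hi - lo)


@dataclass
class Msa:
    """Gapped multiple alignment; row order equals input order."""

    ids: list[str]
    rows: list[str]
    moltype: str = "nucleotide"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_records(self) -> list[SequenceRecord]:
        """Degapped rows as records (for round-tripping)."""
        return [
            SequenceRecord(id=i, residues=r.replace("-", ""), moltype=self.moltype)
            for i, r in zip(self.ids, self.rows)
        ]


def _merge_into_master(
    master: str, rows: list[str], c_aln: str, o_aln: str
) -> tuple[str, list[str], str]:
    """Merge a (center, other) pairwise alignment into the running MSA.

    ``master`` is the center row of the MSA so far; ``c_aln``/``o_aln`` are
    the new pairwise rows.  Once a gap, always a gap.
    """
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_other: list[str] = []
    i = j = 0
    while i < len(master) or j < len(c_aln):
        mi = master[i] if i < len(master) else None
        cj = c_aln[j] if j < len(c_aln) else None
        if mi == "-":
            # old insertion column relative to the center; consumed first
            new_master.append("-")
            for r, nr in zip(rows, new_rows):
                nr.append(r[i])
            new_other.append("-")
            i += 1
            continue
        if cj is not None and cj == "-":
            # new insertion relative to center: open a gap in all old rows
            new_master.append("-")
            for nr in new_rows:
                nr.append("-")
            new_other.append(o_aln[j])
            j += 1
            continue
        # both carry the same center residue
        new_master.append(mi)  # type: ignore[arg-type]
        for r, nr in zip(rows, new_rows):
            nr.append(r[i])
        new_other.append(o_aln[j])
        i += 1
        j += 1
    return "".join(new_master), ["".join(r) for r in new_rows], "".join(new_other)


def star_msa(
    records: list[SequenceRecord], scoring: ScoringScheme | None = None
) -> Msa:
    """Center-star multiple alignment.

    The center is the record maximizing the summed pairwise score to all
    others (ties: first in input order); every other record is merged
    against the center under "once a gap, always a gap".
    """
    if len(records) < 2:
        raise ValueError("star_msa requires at least 2 records")
    moltypes = {r.moltype for r in records}
    if len(moltypes) > 1:
        raise ValueError("mixed moltypes in star_msa input")
    if scoring is None:
        scoring = _default_scoring(records[0].moltype)

    pair_score: dict[tuple[int, int], float] = {}
    pair_aln: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            aln = global_align(records[i], records[j], scoring)
            pair_score[(i, j)] = pair_score[(j, i)] = aln.score
            pair_aln[(i, j)] = aln

    totals = [
        sum(pair_score[(i, j)] for j in range(len(records)) if j != i)
        for i in range(len(records))
    ]
    center = max(range(len(records)), key=lambda i: (totals[i], -i))

    master = records[center].residues
    aligned: dict[int, str] = {center: master}
    order: list[int] = [center]
    rows_so_far: list[str] = [master]
    for k in range(len(records)):
        if k == center:
            continue
        if (center, k) in pair_aln:
            aln = pair_aln[(center, k)]
            c_row, o_row = aln.aligned_query, aln.aligned_target
        else:
            aln = pair_aln[(k, center)]
            c_row, o_row = aln.aligned_target, aln.aligned_query
        master, rows_so_far, new_row = _merge_into_master(
            master, rows_so_far, c_row, o_row
        )
        rows_so_far.append(new_row)
        order.append(k)

    by_index = dict(zip(order, rows_so_far))
    return Msa(
        ids=[r.id for r in records],
        rows=[by_index[i] for i in range(len(records))],
        moltype=records[0].moltype,
    )


def consensus(msa: Msa, majority: float = 0.5) -> tuple[str, list[float]]:
    """Majority-rule consensus with per-column conservation scores.

    Per column the most frequent non-gap residue is emitted if its frequency
    over all rows strictly exceeds ``majority``; otherwise the ambiguity
    character (N for nucleotide, X for protein).  All-gap columns emit "-"
    with conservation 0.
    """
    amb = "N" if msa.moltype == "nucleotide" else "X"
    n_rows = len(msa.rows)
    cons: list[str] = []
    scores: list[float] = []
    for col in range(msa.n_columns):
        counts: dict[str, int] = {}
        for row in msa.rows:
            c = row[col]
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            cons.append("-")
            scores.append(0.0)
            continue
        best = max(counts, key=lambda c: (counts[c], -ord(c)))
        freq = counts[best] / n_rows
        cons.append(best if freq > majority else amb)
        scores.append(freq)
    return "".join(cons), scores
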