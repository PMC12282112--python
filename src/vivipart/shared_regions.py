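"""Identical/near-identical regions shared between segments of one virus.

Shared terminal blocks are the footprint of recombination and segment
duplication in multipartite virus genomes — e.g. two segments whose first
800 nt are identical, or whose 3' ends (poly(A) excluded) agree at 90%.
Detection is exact k-mer seeding followed by greedy ungapped X-drop
extension; terminal identity is an ungapped position-by-position comparison
anchored at the terminus, which matches how such blocks are read off an
alignment figure (a gapped-alignment identity is reported alongside for
transparency).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import global_align, percent_identity
from .core_io import Interval, SequenceRecord
from .terminus import trim_polyA

__all__ = [
    "SharedBlock",
    "longest_common_prefix",
    "longest_common_suffix",
    "terminal_identity",
    "find_shared_blocks",
]


@dataclass
class SharedBlock:
    seg_a: str
    seg_b: str
    location: str  # 5'_terminal | 3'_terminal | internal
    span_a: Interval  # on the poly(A)-trimmed plus strand
    span_b: Interval
    length: int
    identity: float

    def __post_init__(self) -> None:
        if len(self.span_a) != self.length or len(self.span_b) != self.length:
            raise ValueError("span lengths must equal block length (ungapped)")
        if not 0 <= self.identity <= 1:
            raise ValueError("identity outside [0, 1]")


def _nt(rec: SequenceRecord | str) -> str:
    return rec.residues if isinstance(rec, SequenceRecord) else rec


def longest_common_prefix(a: SequenceRecord | str, b: SequenceRecord | str) -> int:
    """Length of the maximal identical 5' prefix."""
    sa, sb = _nt(a), _nt(b)
    n = min(len(sa), len(sb))
    i = 0
    while i < n and sa[i] == sb[i]:
        i += 1
    return i


def longest_common_suffix(
    a: SequenceRecord | str, b: SequenceRecord | str, trim_tail: bool = True
) -> int:
    """Length of the maximal identical 3' suffix, after optional poly(A)
    trimming."""
    sa, sb = _nt(a), _nt(b)
    if trim_tail:
        sa, _ = trim_polyA(sa)
        sb, _ = trim_polyA(sb)
    n = min(len(sa), len(sb))
    i = 0
    while i < n and sa[-1 - i] == sb[-1 - i]:
        i += 1
    return i


def terminal_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    end: str = "3'",
    n: int = 100,
) -> tuple[float, float]:
    """Ungapped identity over the ``n`` terminal residues.

    3' windows are right-aligned after poly(A) trimming.  Returns
    ``(ungapped_identity, gapped_alignment_identity)``; the ungapped value
    is the primary one.
    """
    sa, sb = _nt(a), _nt(b)
    if end == "3'":
        sa, _ = trim_polyA(sa)
        sb, _ = trim_polyA(sb)
    elif end != "5'":
        raise ValueError(f"end must be 5' or 3', got {end!r}")
    if len(sa) < n or len(sb) < n:
        raise ValueError(f"window {n} exceeds a trimmed sequence length")
    wa, wb = (sa[:n], sb[:n]) if end == "5'" else (sa[-n:], sb[-n:])
    matches = sum(1 for x, y in zip(wa, wb) if x == y)
    gapped = percent_identity(
        global_align(
            SequenceRecord("a", wa, moltype="nucleotide"),
            SequenceRecord("b", wb, moltype="nucleotide"),
        ),
        "all_columns",
    )
    return matches / n, gapped


def _extend_seed(
    sa: str, sb: str, i: int, j: int, k: int, x_drop: int,
    match: int = 1, mismatch: int = -2,
) -> tuple[int, int, int]:
    """Greedy ungapped extension of a seed match of length ``k`` at
    (i, j); returns (start_a, end_a) of the max-score extension and its
    match count.  Ties in score resolve to the shorter extension."""
    # right extension
    score = k * match
    best_right, best_right_score, best_right_matches = k, score, k
    matches = k
    off = k
    while i + off < len(sa) and j + off < len(sb):
        if sa[i + off] == sb[j + off]:
            score += match
            matches += 1
        else:
            score += mismatch
        off += 1
        if score > best_right_score:
            best_right_score, best_right, best_right_matches = score, off, matches
        if best_right_score - score > x_drop:
            break
    # left extension
    score = best_right_score
    matches = best_right_matches
    best_left, best_left_score, best_left_matches = 0, score, matches
    off = 1
    while i - off >= 0 and j - off >= 0:
        if sa[i - off] == sb[j - off]:
            score += match
            matches += 1
        else:
            score += mismatch
        if score > best_left_score:
            best_left_score, best_left, best_left_matches = score, off, matches
        if best_left_score - score > x_drop:
            break
        off += 1
    return i - best_left, i + best_right, best_left_matches


def _pair_blocks(
    rec_a: SequenceRecord,
    rec_b: SequenceRecord,
    min_len: int,
    min_identity: float,
    k: int,
    x_drop: int,
) -> list[SharedBlock]:
    sa, _ = trim_polyA(rec_a.residues)
    sb, _ = trim_polyA(rec_b.residues)
    if len(sa) < k or len(sb) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(sa) - k + 1):
        index.setdefault(sa[i : i + k], []).append(i)

    # per-diagonal intervals already covered by an extension
    covered: dict[int, list[tuple[int, int]]] = {}
    found: dict[tuple[int, int, int], int] = {}  # (diag, start_a, end_a) -> matches
    for j in range(len(sb) - k + 1):
        kmer = sb[j : j + k]
        for i in index.get(kmer, ()):
            diag = j - i
            skip = False
            for s, e in covered.get(diag, ()):
                if s <= i and i + k <= e:
                    skip = True
                    break
            if skip:
                continue
            start_a, end_a, matches = _extend_seed(sa, sb, i, j, k, x_drop)
            covered.setdefault(diag, []).append((start_a, end_a))
            key = (diag, start_a, end_a)
            found[key] = matches

    # merge overlapping extensions on the same diagonal
    merged: list[tuple[int, int, int]] = []  # (diag, start_a, end_a)
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for (diag, s, e) in found:
        by_diag.setdefault(diag, []).append((s, e))
    for diag, spans in by_diag.items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((diag, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((diag, cur_s, cur_e))

    blocks: list[SharedBlock] = []
    for diag, s, e in merged:
        length = e - s
        if length < min_len:
            continue
        span_a = Interval(s, e)
        span_b = Interval(s + diag, e + diag)
        matches = sum(
            1 for x, y in zip(sa[s:e], sb[span_b.start : span_b.end]) if x == y
        )
        identity = matches / length
        if identity < min_identity:
            continue
        if span_a.start == 0 and span_b.start == 0:
            location = "5'_terminal"
        elif span_a.end == len(sa) and span_b.end == len(sb):
            location = "3'_terminal"
        else:
            location = "internal"
        blocks.append(
            SharedBlock(
                seg_a=rec_a.id, seg_b=rec_b.id, location=location,
                span_a=span_a, span_b=span_b, length=length, identity=identity,
            )
        )
    blocks.sort(key=lambda b: (b.span_a.start, b.span_b.start))
    return blocks


def find_shared_blocks(
    members: list[SequenceRecord],
    min_len: int = 50,
    min_identity: float = 0.8,
    k: int = 15,
    x_drop: int = 10,
) -> list[SharedBlock]:
    """Shared blocks between all member pairs of one virus bundle.

    Seeds are exact ``k``-mers (k = 15: shorter seeds match by chance too
    often between unrelated multi-kb segments); extension is greedy ungapped
    with an X-drop of ``x_drop`` under +1/-2 scoring; overlapping extensions
    on one diagonal are merged, so reported blocks are maximal.  Ordering is
    deterministic: seg_a < seg_b lexicographically, then span_a.start.
    """
    if len(members) < 2:
        raise ValueError("find_shared_blocks requires >= 2 members")
    ordered = sorted(members, key=lambda r: r.id)
    blocks: list[SharedBlock] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            blocks.extend(
                _pair_blocks(ordered[i], ordered[j], min_len, min_identity,
                             k, x_drop)
            )
    blocks.sort(key=lambda b: (b.seg_a, b.seg_b, b.span_a.start))
    return blocks
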