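"""Terminal-sequence signals that unite segments into one genome.

Segments of a multipartite +ssRNA virus share a conserved ~80-nt 5' motif
(carrying a tandem pentanucleotide repeat such as (CAAAA)7-8) and a 3'
poly(A) tail.  This module provides poly(A) trimming, terminal windows,
exact tandem-repeat detection, star-MSA terminal profiles and an estimate
of the conserved terminal length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import Msa, consensus, global_align, percent_identity, star_msa
from .core_io import Interval, SequenceRecord

__all__ = [
    "RepeatHit",
    "TerminalProfile",
    "trim_polyA",
    "max_tandem_repeat",
    "terminal_window",
    "build_terminal_profile",
    "conserved_terminal_length",
]


@dataclass(frozen=True)
class RepeatHit:
    """Maximal exact tandem repeat of ``unit`` (``copies`` >= 1)."""

    unit: str
    copies: int
    span: Interval

    def __post_init__(self) -> None:
        if len(self.span) != self.copies * len(self.unit):
            raise ValueError("span length != copies * unit length")


@dataclass
class TerminalProfile:
    """Consensus 5' terminal window of one virus bundle."""

    virus_id: str
    window_length: int
    consensus: str
    per_column_conservation: list[float]
    #: per-member repeat summary (member id -> RepeatHit or None)
    repeat: dict[str, RepeatHit | None]

    def __post_init__(self) -> None:
        if len(self.consensus) != self.window_length:
            raise ValueError("consensus length != window_length")
        if any(not 0 <= c <= 1 for c in self.per_column_conservation):
            raise ValueError("conservation outside [0, 1]")


def trim_polyA(seq: str, min_run: int = 8) -> tuple[str, int]:
    """Remove the maximal terminal run of A if it is at least ``min_run``.

    The rule is exact-run (no mismatches): deposited tails are
    homopolymeric, and a permissive rule could eat genuine 3' sequence.
    Returns ``(trimmed, tail_length)``; shorter runs leave the input
    unchanged with tail_length 0.
    """
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    run = n - i
    if run >= min_run:
        return seq[:i], run
    return seq, 0


#: sentinel for a unit absent from the search window
NO_HIT = None


def max_tandem_repeat(
    seq: str, unit: str, search_window: Interval | None = None
) -> RepeatHit | None:
    """Maximal exact tandem repeat of ``unit`` inside ``search_window``.

    Degenerate copies terminate the tandem (the repeat is a strict unit).
    Ties on copy number break to the smallest start.  Returns ``None`` if
    the unit does not occur at all.
    """
    if len(unit) < 2:
        raise ValueError("repeat unit must have length >= 2")
    if search_window is None:
        search_window = Interval(0, len(seq))
    if search_window.end > len(seq):
        raise ValueError("search window exceeds sequence")
    window = seq[search_window.start : search_window.end]
    if not window:
        raise ValueError("empty search window")

    u = len(unit)
    best: tuple[int, int] | None = None  # (copies, start-in-window)
    i = 0
    while i + u <= len(window):
        if window[i : i + u] != unit:
            i += 1
            continue
        copies = 1
        while window[i + copies * u : i + (copies + 1) * u] == unit:
            copies += 1
        if best is None or copies > best[0]:
            best = (copies, i)
        i += 1
    if best is None:
        return NO_HIT
    copies, start = best
    abs_start = search_window.start + start
    return RepeatHit(unit=unit, copies=copies,
                     span=Interval(abs_start, abs_start + copies * u))


def terminal_window(seq: str, n: int = 100, end: str = "5'") -> str:
    """First/last ``min(n, len)`` residues; 3' windows are taken after
    poly(A) trimming."""
    if n < 1:
        raise ValueError("window size must be >= 1")
    if end == "5'":
        return seq[:n]
    if end == "3'":
        trimmed, _ = trim_polyA(seq)
        return trimmed[-n:]
    raise ValueError(f"end must be 5' or 3', got {end!r}")


def build_terminal_profile(
    members: list[SequenceRecord],
    window: int = 100,
    virus_id: str = "",
    repeat_unit: str = "CAAAA",
) -> TerminalProfile:
    """Star-MSA the members' 5' windows into a consensus profile.

    Also records the maximal tandem repeat of ``repeat_unit`` within each
    member's window.
    """
    if len(members) < 2:
        raise ValueError("terminal profile requires >= 2 members")
    windows = [
        SequenceRecord(id=m.id, residues=terminal_window(m.residues, window),
                       moltype="nucleotide")
        for m in members
    ]
    msa: Msa = star_msa(windows)
    cons, scores = consensus(msa)
    repeats = {
        m.id: max_tandem_repeat(w.residues, repeat_unit)
        for m, w in zip(members, windows)
    }
    return TerminalProfile(
        virus_id=virus_id or members[0].id,
        window_length=len(cons),
        consensus=cons,
        per_column_conservation=scores,
        repeat=repeats,
    )


def conserved_terminal_length(
    members: list[SequenceRecord],
    identity_threshold: float = 0.9,
    step: int = 5,
    max_length: int = 200,
) -> int:
    """Largest window length L (multiple of ``step``) whose mean pairwise
    5'-window identity (global alignment, all columns) meets the threshold.

    Reported in steps of ``step`` nt: single-nucleotide resolution is noise
    at a few percent terminal divergence.  Returns 0 if no window length
    qualifies.  Monotone non-increasing in the threshold by construction.
    """
    if len(members) < 2:
        raise ValueError("conserved_terminal_length requires >= 2 members")
    limit = min(min(len(m.residues) for m in members), max_length)
    best = 0
    for length in range(step, limit + 1, step):
        windows = [
            SequenceRecord(id=m.id, residues=m.residues[:length],
                           moltype="nucleotide")
            for m in members
        ]
        idents = []
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                aln = global_align(windows[i], windows[j])
                idents.append(percent_identity(aln, "all_columns"))
        if sum(idents) / len(idents) >= identity_threshold:
            best = length
    return best
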