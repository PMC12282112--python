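"""Spot checks against a deposited 10-segment vivivirid genome.

Given the ten genomic segments of Fusarium asiaticum vivivirus 1 (GenBank
PP100127-PP100136, converted to FASTA by the user; this package performs no
network access), recompute the headline genome features: segment length
extremes, the identical S9/S10 5' prefix, the identical S8/S10 3' suffix,
the S9/S10 3'-block identity, the S9 ORF protein length, and the terminal
CAAAA tandem copy number.
"""

from __future__ import annotations

import re

from .annotate import find_orfs
from .core_io import SequenceRecord, read_fasta
from .shared_regions import (
    longest_common_prefix,
    longest_common_suffix,
    terminal_identity,
)
from .terminus import conserved_terminal_length, max_tandem_repeat, trim_polyA

__all__ = ["favvv1_spot_check"]

_SEG_RE = re.compile(r"[Ss](\d{1,2})\b")


def _segment_map(records: list[SequenceRecord]) -> dict[int, SequenceRecord]:
    """Map segment number -> record, from 'S<k>' tokens in ids/descriptions
    or, failing that, from input order (first record = S1)."""
    mapping: dict[int, SequenceRecord] = {}
    for rec in records:
        m = _SEG_RE.search(rec.id) or _SEG_RE.search(rec.description)
        if m:
            mapping[int(m.group(1))] = rec
    if len(mapping) != len(records):
        mapping = {i + 1: rec for i, rec in enumerate(records)}
    return mapping


def favvv1_spot_check(path_or_records) -> dict[str, float]:
    """Recompute the deposited genome's printed features.

    Accepts a FASTA path or a list of the ten segment records (S1-S10).
    Returns a dict of quantities on the scale they are conventionally
    reported (identities as percentages).
    """
    if isinstance(path_or_records, (str, bytes)) or hasattr(path_or_records, "__fspath__"):
        records = read_fasta(path_or_records, moltype="nucleotide")
    else:
        records = list(path_or_records)
    if len(records) != 10:
        raise ValueError(f"expected the 10 genomic segments, got {len(records)}")
    segs = _segment_map(records)

    lengths = [len(r.residues) for r in records]
    s8, s9, s10 = segs[8], segs[9], segs[10]
    ident_101, _ = terminal_identity(s9, s10, "3'", 101)

    orfs_s9 = find_orfs(s9.residues, min_aa=50)
    if not orfs_s9:
        raise ValueError("no ORF of >= 50 aa found on S9")

    repeat_copies = []
    for rec in records:
        trimmed, _ = trim_polyA(rec.residues)
        hit = max_tandem_repeat(trimmed[:120], "CAAAA")
        repeat_copies.append(hit.copies if hit else 0)

    return {
        "segment_length_min": float(min(lengths)),
        "segment_length_max": float(max(lengths)),
        "s9_s10_identical_prefix_nt": float(longest_common_prefix(s9, s10)),
        "s8_s10_identical_suffix_nt": float(longest_common_suffix(s8, s10)),
        "s9_s10_3prime_block_identity_pct": round(ident_101 * 100, 1),
        "s9_orf_protein_aa": float(len(orfs_s9[0].protein)),
        "terminal_repeat_copies_max": float(max(repeat_copies)),
        "conserved_terminal_length_nt": float(
            conserved_terminal_length(records)
        ),
    }
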