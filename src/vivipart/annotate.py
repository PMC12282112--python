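"""ORF prediction, peptide-evidence start sites, diagnostic motifs and mass.

The diagnostic motifs are the field's signatures for the conserved segment
proteins of vivivirids: the canonical methyltransferase (H ... DXG ... DXXR),
the chymotrypsin-type serine protease triad (His/Asp/Ser) and the
papain-like cysteine protease (GXCY ... H/R ... [VILM]G|G, cleaving between
the two glycines).  Motif content is fixed; the spacer bounds bracket the
FaVvV1 exemplars and live in a user-extensible YAML catalog.

ORF reports use 1-based inclusive coordinates (GenBank convention); the
internal model stays 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml
from Bio.SeqUtils import molecular_weight as _bio_mw

from .core_io import Interval, translate

__all__ = [
    "OrfRecord",
    "MotifDefinition",
    "MotifHit",
    "PeptideEvidence",
    "CoverageResult",
    "find_orfs",
    "peptide_coverage",
    "refine_start",
    "scan_motif",
    "predict_cleavage",
    "molecular_weight",
    "load_motif_catalog",
]

_STOPS = frozenset(["TAA", "TAG", "TGA"])


@dataclass
class OrfRecord:
    """Plus-strand ORF; ``nt_span`` includes the stop codon."""

    contig_id: str
    nt_span: Interval
    frame: int
    protein: str  # no stop character
    start_codon_rank: int = 1

    def __post_init__(self) -> None:
        if len(self.nt_span) % 3 != 0:
            raise ValueError("ORF span not divisible by 3")
        if self.start_codon_rank < 1:
            raise ValueError("start_codon_rank must be >= 1")

    def met_offsets(self) -> list[int]:
        """0-based protein offsets of in-frame AUGs (rank r = r-th entry)."""
        return [i for i, aa in enumerate(self.protein) if aa == "M"]


def find_orfs(seq: str, min_aa: int = 50, require_atg: bool = True) -> list[OrfRecord]:
    """All maximal AUG-to-stop ORFs in the three plus-strand frames.

    Maximal means the 5'-most AUG after the previous in-frame stop; internal
    AUGs are start-codon candidates of the same ORF, not separate ORFs.
    Sorted by protein length descending, then nucleotide start, then frame.
    """
    seq = seq.upper().replace("U", "T")
    orfs: list[OrfRecord] = []
    for frame in range(3):
        start: int | None = None  # nt position of the current ORF's AUG
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    protein = translate(seq[start : i], 0)
                    if len(protein) >= min_aa and "*" not in protein:
                        orfs.append(
                            OrfRecord(
                                contig_id="",
                                nt_span=Interval(start, i + 3),
                                frame=frame,
                                protein=protein,
                            )
                        )
                    start = None
            elif start is None and (codon == "ATG" or not require_atg):
                start = i
    orfs.sort(key=lambda o: (-len(o.protein), o.nt_span.start, o.frame))
    return orfs


@dataclass(frozen=True)
class PeptideEvidence:
    """One mass-spectrometry peptide matched against a target protein."""

    peptide: str
    n_terminal_acetyl: bool = False

    def __post_init__(self) -> None:
        if len(self.peptide) < 6:
            raise ValueError("peptide length must be >= 6")


@dataclass
class CoverageResult:
    covered: list[Interval]  # merged, sorted, 0-based half-open
    first_match_position: int | None  # 1-based residue index
    uncovered_n_terminal: int
    unmatched: list[str]
    #: 1-based start positions of matched acetylated peptides
    acetyl_starts: list[int] = field(default_factory=list)


def _collapse_il(s: str) -> str:
    # mass spectrometry cannot distinguish isoleucine from leucine
    return s.replace("I", "L")


def peptide_coverage(protein: str, peptides: list[PeptideEvidence]) -> CoverageResult:
    """Union of exact peptide matches (I/L collapsed) on ``protein``.

    The uncovered N-terminal length is ``first_match_position - 1`` in the
    1-based report convention; peptides matching nowhere are listed, not an
    error.
    """
    target = _collapse_il(protein.upper())
    raw: list[tuple[int, int]] = []
    unmatched: list[str] = []
    acetyl_starts: list[int] = []
    for pep in peptides:
        query = _collapse_il(pep.peptide.upper())
        found = False
        start = target.find(query)
        while start != -1:
            raw.append((start, start + len(query)))
            if pep.n_terminal_acetyl:
                acetyl_starts.append(start + 1)
            found = True
            start = target.find(query, start + 1)
        if not found:
            unmatched.append(pep.peptide)
    raw.sort()
    merged: list[Interval] = []
    for s, e in raw:
        if merged and s <= merged[-1].end:
            if e > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, e)
        else:
            merged.append(Interval(s, e))
    first = merged[0].start + 1 if merged else None
    return CoverageResult(
        covered=merged,
        first_match_position=first,
        uncovered_n_terminal=(first - 1) if first is not None else len(protein),
        unmatched=unmatched,
        acetyl_starts=sorted(set(acetyl_starts)),
    )


def refine_start(
    orf: OrfRecord,
    coverage: CoverageResult,
    max_rank: int = 3,
    allowed_overhang: int = 0,
) -> tuple[int, str]:
    """Propose a start-codon rank from peptide evidence.

    Coverage must have been computed against the rank-1 protein.  Among the
    first ``max_rank`` in-frame AUGs, the largest-rank AUG at or before
    ``first_match_position - allowed_overhang`` is proposed when an
    N-terminally acetylated peptide starts exactly at that AUG's first
    residue; both initiator-Met-retained and Met-cleaved N-termini are
    accepted, since acetylation evidence does not resolve Met processing.
    Without acetyl evidence the rank-1 start is kept, flagged "unrefined".
    """
    if not coverage.acetyl_starts:
        return 1, "unrefined: no N-terminally acetylated peptide evidence"
    if coverage.first_match_position is None:
        return 1, "unrefined: no peptide matched the rank-1 protein"
    mets = orf.met_offsets()[:max_rank]
    limit = coverage.first_match_position - allowed_overhang
    for rank in range(len(mets), 0, -1):
        met0 = mets[rank - 1]  # 0-based offset of this AUG's Met in rank-1
        if met0 + 1 > limit:
            continue
        retained = met0 + 1 in coverage.acetyl_starts
        cleaved = met0 + 2 in coverage.acetyl_starts
        if retained or cleaved:
            policy = "Met-retained" if retained else "Met-cleaved"
            return rank, (
                f"acetylated peptide pins the N-terminus at rank-{rank} AUG "
                f"({policy})"
            )
    return 1, "unrefined: acetyl evidence does not match a candidate AUG"


@dataclass(frozen=True)
class MotifDefinition:
    """Ordered residue-class blocks separated by bounded spacers.

    Each block is a tuple of residue classes; a class is a string of allowed
    residues, with "x" meaning any residue.  ``spacers[i]`` bounds the
    number of residues strictly between block i and block i+1.
    """

    name: str
    blocks: tuple[tuple[str, ...], ...]
    spacers: tuple[tuple[int, int], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.blocks) - 1:
            raise ValueError("need exactly len(blocks) - 1 spacers")
        for lo, hi in self.spacers:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid spacer bounds ({lo}, {hi})")


@dataclass
class MotifHit:
    motif: str
    protein_id: str
    #: 0-based start position of each block
    block_starts: tuple[int, ...]
    matched: tuple[str, ...]

    @property
    def report_positions(self) -> tuple[int, ...]:
        """1-based block start positions for rendered reports."""
        return tuple(p + 1 for p in self.block_starts)


def _class_matches(aa: str, cls: str) -> bool:
    return cls == "x" or aa in cls


def _block_starts(protein: str, block: tuple[str, ...]) -> list[int]:
    n, b = len(protein), len(block)
    return [
        i
        for i in range(n - b + 1)
        if all(_class_matches(protein[i + k], block[k]) for k in range(b))
    ]


def scan_motif(
    protein: str, motif: MotifDefinition, protein_id: str = ""
) -> list[MotifHit]:
    """All placements of ``motif`` on ``protein``; overlapping hits are all
    reported.  Equivalent to exhaustive placement enumeration."""
    protein = protein.upper()
    if not protein:
        return []
    candidates = [_block_starts(protein, b) for b in motif.blocks]
    hits: list[MotifHit] = []

    def extend(idx: int, chosen: list[int]) -> None:
        if idx == len(motif.blocks):
            matched = tuple(
                protein[s : s + len(b)] for s, b in zip(chosen, motif.blocks)
            )
            hits.append(
                MotifHit(motif=motif.name, protein_id=protein_id,
                         block_starts=tuple(chosen), matched=matched)
            )
            return
        prev_end = chosen[-1] + len(motif.blocks[idx - 1])
        lo, hi = motif.spacers[idx - 1]
        for s in candidates[idx]:
            gap = s - prev_end
            if gap < lo:
                continue
            if gap > hi:
                break
            extend(idx + 1, chosen + [s])

    for s0 in candidates[0]:
        extend(1, [s0])
    return hits


def predict_cleavage(protein: str) -> list[int]:
    """[VILM]G|G sites: 1-based position of the residue preceding the
    scissile bond (cleavage falls between the two glycines)."""
    protein = protein.upper()
    return [
        i + 2
        for i in range(len(protein) - 2)
        if protein[i] in "VILM" and protein[i + 1] == "G" and protein[i + 2] == "G"
    ]


def molecular_weight(protein: str) -> float:
    """Average (isotope-averaged) protein mass in kDa.

    Rendered reports print it to 2 decimals; the value itself is exact.
    """
    protein = protein.upper()
    bad = [i + 1 for i, aa in enumerate(protein) if aa in "X*"]
    if bad:
        raise ValueError(
            f"ambiguous/stop residues at 1-based positions {bad}; "
            "mass is undefined"
        )
    return _bio_mw(protein, seq_type="protein") / 1000.0


def load_motif_catalog(path=None) -> dict[str, MotifDefinition]:
    """Load motif definitions from YAML (the packaged catalog by default)."""
    if path is None:
        text = (
            resources.files("vivipart").joinpath("data/motifs.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    catalog: dict[str, MotifDefinition] = {}
    for name, spec in raw.items():
        catalog[name] = MotifDefinition(
            name=name,
            blocks=tuple(tuple(str(c) for c in block) for block in spec["blocks"]),
            spacers=tuple((int(lo), int(hi)) for lo, hi in spec["spacers"]),
            description=spec.get("description", ""),
        )
    return catalog
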