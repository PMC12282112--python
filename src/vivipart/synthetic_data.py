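"""Synthetic multipartite virus genome sets with planted ground truth.

The generator emulates the genome architecture of vivivirid-like
multipartite +ssRNA viruses: every segment of one virus carries an
independently mutated copy of that virus's conserved 5' terminal motif
(~80 nt, containing a (CAAAA)7-8-type tandem repeat), a body with exactly
one plus-strand ORF, and a 3' poly(A) tail.  Homologous segments across
viruses encode mutated copies of a shared protein-cassette library, so
homolog clustering has a recoverable target; segments beyond the cassette
library carry virus-unique "orphan" proteins, mirroring the unique segments
real viruses show.  Planted structure includes near-identical duplicated
segments, identical/near-identical inter-segment terminal blocks (the
S8/S9/S10-style recombination signature) and decoy host-like contigs that
carry a poly(A) tail but no terminal motif and no cassette.

Everything planted is recorded in a :class:`GroundTruth` whose quantities
are recomputed from the emitted sequences, so downstream recovery can be
scored exactly.  A fixed seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import find_orfs
from .core_io import Interval, SequenceRecord, reverse_complement, translate, write_fasta
from .terminus import max_tandem_repeat

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SharedBlockSpec",
    "simulate",
    "plant_shared_blocks",
    "emit",
]

_BASES = "ACGT"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# reverse codon table (standard code, stops excluded), deterministic order
_CODONS_FOR: dict[str, list[str]] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _codon = _b1 + _b2 + _b3
            _aa = translate(_codon)
            if _aa != "*":
                _CODONS_FOR.setdefault(_aa, []).append(_codon)

_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SharedBlockSpec:
    """A planted terminal block copied from ``donor`` into ``acceptor``."""

    donor: str
    acceptor: str
    end: str  # "5'" or "3'"
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.end not in ("5'", "3'"):
            raise ValueError("end must be 5' or 3'")
        if self.length < 1 or not 0 < self.identity <= 1:
            raise ValueError("invalid block length/identity")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_viruses: tuple[int, int] = (3, 5)
    segments_per_virus: tuple[int, int] = (5, 12)
    segment_length: tuple[int, int] = (1000, 3700)
    terminal_motif_length: int = 80
    repeat_unit: str = "CAAAA"
    repeat_copies: tuple[int, int] = (7, 8)
    polyA_length: tuple[int, int] = (15, 40)
    #: per-site substitution probability applied to each segment's copy of
    #: its virus's terminal motif
    terminal_divergence: float = 0.03
    n_duplicated_segments: tuple[int, int] = (0, 2)
    #: terminal blocks planted between three designated segments of the
    #: first virus: (end, length, identity)
    shared_block_specs: tuple[tuple[str, int, float], ...] = (
        ("5'", 800, 1.0),
        ("3'", 263, 1.0),
        ("3'", 101, 0.90),
    )
    n_decoys: int | None = None  # default: decoy_fraction of segment count
    decoy_fraction: float = 0.2
    decoy_length: tuple[int, int] = (1000, 3700)
    orf_min_aa: int = 50
    #: per-residue divergence of each virus's cassette copies from the
    #: shared library (keeps homologs detectably similar)
    cassette_divergence: float = 0.05
    #: per-site divergence of duplicated-segment near-copies
    duplicate_divergence: float = 0.02
    #: chance plus-strand ORFs at least this long (other than the planted
    #: one) are mutated away so the planted ORF is unambiguously longest
    spurious_orf_max_aa: int = 60
    #: fraction of non-decoy contigs emitted reverse-complemented
    reverse_fraction: float = 0.5
    coverage_segment_mean: float = 200.0
    coverage_decoy_mean: float = 5.0

    def __post_init__(self) -> None:
        for lo, hi in (self.n_viruses, self.segments_per_virus,
                       self.segment_length, self.polyA_length,
                       self.repeat_copies, self.n_duplicated_segments,
                       self.decoy_length):
            if lo > hi:
                raise ValueError(f"empty range ({lo}, {hi})")
        for p in (self.terminal_divergence, self.cassette_divergence,
                  self.duplicate_divergence, self.decoy_fraction,
                  self.reverse_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.repeat_copies[1] * len(self.repeat_unit) + 10 > self.terminal_motif_length:
            raise ValueError("tandem repeat does not fit inside the terminal motif")


@dataclass
class GroundTruth:
    """Planted structure, with realized (recomputed) quantities.

    All coordinates are 0-based half-open on the plus strand of each
    contig; ``orientation`` records which strand each contig was emitted
    on, so plus-strand sequences are recovered by reverse-complementing
    '-' contigs.
    """

    membership: dict[str, str] = field(default_factory=dict)
    segment_class: dict[str, str] = field(default_factory=dict)
    planted_blocks: list[dict] = field(default_factory=list)
    planted_orfs: dict[str, dict] = field(default_factory=dict)
    planted_repeats: dict[str, int] = field(default_factory=dict)
    orientation: dict[str, str] = field(default_factory=dict)
    anchors: list[str] = field(default_factory=list)
    virus_motifs: dict[str, str] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)

    def duplication_events(self) -> dict[tuple[str, str], int]:
        """Planted (virus, class) -> copy count for counts >= 2."""
        counts: dict[tuple[str, str], int] = {}
        for contig, virus in self.membership.items():
            if virus == "decoy":
                continue
            key = (virus, self.segment_class[contig])
            counts[key] = counts.get(key, 0) + 1
        return {k: v for k, v in counts.items() if v >= 2}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(**raw)


# ---------------------------------------------------------------------------
# internal segment representation


@dataclass
class _Seg:
    id: str
    virus: str
    body: list[str]  # plus-strand, poly(A) excluded
    tail: int
    klass: str
    orf: tuple[int, int, int] | None  # (start, end incl. stop, frame)
    protected: set[int] = field(default_factory=set)


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _rand_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "M" + "".join(_AA20[i] for i in rng.integers(0, 20, size=n_aa - 1))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # initiator Met kept
        if rng.random() < rate:
            choices = _AA20.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = _BASES.replace(out[i], "")
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for i, aa in enumerate(protein):
        if i == 0:
            codons.append("ATG")
            continue
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _make_motif(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    copies = int(rng.integers(cfg.repeat_copies[0], cfg.repeat_copies[1] + 1))
    repeat = cfg.repeat_unit * copies
    slack = cfg.terminal_motif_length - len(repeat)
    prefix_len = int(rng.integers(5, slack - 4))
    motif = (
        _rand_nt(rng, prefix_len)
        + repeat
        + _rand_nt(rng, slack - prefix_len)
    )
    return motif


def _force_stop_synonymously(seg: _Seg, s: int, e: int) -> bool:
    """Create a stop codon in the offender frame [s, e) by recoding planted
    CDS codons synonymously (and freely editing unprotected positions).

    Returns True when a stop was introduced.  The planted protein, the ATG
    and the terminal stop are never altered.
    """
    cds_s, cds_e, _f = seg.orf if seg.orf is not None else (-1, -1, 0)
    for p in range(s + 3, e - 4, 3):  # stop start, offender frame, keep ATG
        for stop in _STOP_CODONS:
            need = [(p + k, stop[k]) for k in range(3)
                    if seg.body[p + k] != stop[k]]
            if not need:
                continue
            # group required base changes by planted-CDS codon
            per_codon: dict[int, list[tuple[int, str]]] = {}
            free: list[tuple[int, str]] = []
            ok = True
            for pos, base in need:
                if cds_s <= pos < cds_e:
                    cc = cds_s + ((pos - cds_s) // 3) * 3
                    if cc == cds_s or cc >= cds_e - 3:
                        ok = False  # ATG or terminal stop codon
                        break
                    per_codon.setdefault(cc, []).append((pos - cc, base))
                elif pos in seg.protected:
                    ok = False
                    break
                else:
                    free.append((pos, base))
            if not ok:
                continue
            replacements: dict[int, str] = {}
            for cc, reqs in per_codon.items():
                codon = "".join(seg.body[cc : cc + 3])
                aa = translate(codon)
                option = next(
                    (
                        c for c in _CODONS_FOR.get(aa, [])
                        if all(c[k] == b for k, b in reqs)
                    ),
                    None,
                )
                if option is None:
                    ok = False
                    break
                replacements[cc] = option
            if not ok:
                continue
            for pos, base in free:
                seg.body[pos] = base
            for cc, option in replacements.items():
                for k in range(3):
                    seg.body[cc + k] = option[k]
            return True
    return False


def _repair_spurious_orfs(seg: _Seg, cfg: SimulationConfig,
                          rng: np.random.Generator) -> None:
    """Mutate away chance plus-strand ORFs that could outcompete the
    planted one.

    An offender is any non-planted ORF long enough to rival the planted
    protein (within a 10-aa safety margin) or, absent a planted ORF, any
    ORF of at least ``spurious_orf_max_aa``.  Only unprotected positions
    are mutated freely (protected positions cover the terminal motif, the
    planted CDS with its upstream in-frame stop guard, and planted shared
    blocks); offenders buried in protected coding sequence are broken by
    synonymous recoding, so planted quantities stay byte-exact.
    """
    if seg.orf is not None:
        planted_aa = (seg.orf[1] - seg.orf[0]) // 3 - 1
        threshold = max(planted_aa - 10, 30)
    else:
        threshold = cfg.spurious_orf_max_aa
    for _ in range(300):
        seq = "".join(seg.body)
        offenders = [
            o for o in find_orfs(seq, min_aa=threshold)
            if seg.orf is None
            or (o.nt_span.start, o.nt_span.end) != (seg.orf[0], seg.orf[1])
        ]
        if not offenders:
            return
        orf = offenders[0]
        s, e = orf.nt_span.start, orf.nt_span.end
        # candidate stop insertions, middle-out over codons of the ORF frame
        codon_starts = list(range(s + 3, e - 2, 3))
        codon_starts.sort(key=lambda c: abs(c - (s + e) // 2))
        applied = False
        for cs in codon_starts:
            for stop in _STOP_CODONS:
                need = [
                    (cs + k, stop[k])
                    for k in range(3)
                    if seg.body[cs + k] != stop[k]
                ]
                if need and all(p not in seg.protected for p, _ in need):
                    for p, base in need:
                        seg.body[p] = base
                    applied = True
                    break
            if applied:
                break
        if not applied and not _force_stop_synonymously(seg, s, e):
            raise RuntimeError(
                f"cannot break spurious ORF at {s}-{e} in {seg.id}"
            )
    raise RuntimeError(f"spurious-ORF repair did not converge for {seg.id}")


def _build_segment(
    seg_id: str,
    virus: str,
    motif: str,
    protein: str | None,
    klass: str,
    target_len: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> _Seg:
    """Assemble motif + 5'UTR + guarded CDS + 3'UTR (poly(A) kept aside)."""
    motif_seg = _mutate_nt(rng, motif, cfg.terminal_divergence)
    parts = [motif_seg]
    protected = set(range(len(motif_seg)))
    orf = None
    if protein is not None:
        utr5 = list(_rand_nt(rng, int(rng.integers(15, 61))))
        utr5[-3:] = "TAA"  # in-frame stop guard: no upstream AUG can run on
        cds = _reverse_translate(rng, protein)
        start = len(motif_seg) + len(utr5)
        orf = (start, start + len(cds), start % 3)
        protected.update(range(start - 3, start + len(cds)))
        parts.append("".join(utr5))
        parts.append(cds)
    built = sum(len(p) for p in parts)
    utr3_len = max(target_len - built, 30)
    parts.append(_rand_nt(rng, utr3_len))
    body = list("".join(parts))
    if body[-1] == "A":
        # keep the poly(A) boundary unambiguous under exact-run trimming
        body[-1] = "CGT"[rng.integers(0, 3)]
    tail = int(rng.integers(cfg.polyA_length[0], cfg.polyA_length[1] + 1))
    seg = _Seg(id=seg_id, virus=virus, body=body, tail=tail, klass=klass,
               orf=orf, protected=protected)
    _repair_spurious_orfs(seg, cfg, rng)
    return seg


def _cassette_library(cfg: SimulationConfig, rng: np.random.Generator):
    """8 shared protein cassettes (80-300 aa) mimicking the conserved
    segment content of multipartite vivivirid genomes."""
    names = ["RdRP", "MtrHel", "CSPro", "PCProA", "SF2H", "PCProB", "CP", "HP"]
    lengths = [300, 280, 240, 160, 220, 140, 200, 100]
    return {
        f"cassette_{name}": _rand_protein(rng, n)
        for name, n in zip(names, lengths)
    }


def plant_shared_blocks(
    segs: list[_Seg],
    truth: GroundTruth,
    spec: SharedBlockSpec,
    rng: np.random.Generator,
    repeat_unit: str = "CAAAA",
) -> None:
    """Copy a terminal region from donor to acceptor at a target identity.

    Substitution count is ``round((1 - identity) * length)``; positions are
    drawn without replacement and never inside the first tandem-repeat
    region.  The position immediately beyond the block is forced to differ
    so the planted block is maximal.  Coordinates are on the poly(A)-trimmed
    plus strand; truth records the realized identity recomputed from the
    final sequences.
    """
    by_id = {s.id: s for s in segs}
    donor, acceptor = by_id[spec.donor], by_id[spec.acceptor]
    if donor.virus != acceptor.virus:
        raise ValueError("shared blocks are planted within one virus")
    L = spec.length
    if L > len(donor.body) or L >= len(acceptor.body):
        raise ValueError("block longer than a segment body")

    if spec.end == "5'":
        donor_region = donor.body[:L]
        # transfer of the donor ORF must be all-or-nothing
        if acceptor.orf is not None and acceptor.orf[0] < L:
            raise ValueError("block would truncate the acceptor ORF")
        acceptor.body[:L] = donor_region
        if donor.orf is not None and donor.orf[1] <= L:
            acceptor.orf = donor.orf
            acceptor.klass = donor.klass
            truth.segment_class[acceptor.id] = donor.klass
            truth.planted_orfs[acceptor.id] = {
                "start": donor.orf[0], "end": donor.orf[1],
                "frame": donor.orf[2], "rank": 1,
            }
        offsets = (0, 0)
        boundary = L  # acceptor position forced to differ from donor
        donor_boundary_base = donor.body[L] if L < len(donor.body) else None
    else:
        donor_region = donor.body[-L:]
        if acceptor.orf is not None and acceptor.orf[1] > len(acceptor.body) - L:
            raise ValueError("block would truncate the acceptor ORF")
        acceptor.body[-L:] = donor_region
        offsets = (len(donor.body) - L, len(acceptor.body) - L)
        boundary = len(acceptor.body) - L - 1
        donor_boundary_base = (
            donor.body[-L - 1] if L + 1 <= len(donor.body) else None
        )

    # forbidden substitution zone: the first tandem-repeat region
    forbidden: set[int] = set()
    if spec.end == "5'":
        hit = max_tandem_repeat("".join(acceptor.body[:L]), repeat_unit)
        if hit is not None:
            forbidden = set(range(hit.span.start, hit.span.end))

    n_sub = round((1 - spec.identity) * L)
    if spec.end == "5'":
        candidates = [p for p in range(L) if p not in forbidden]
    else:
        # the terminal base stays non-A so the poly(A) boundary is unambiguous
        candidates = list(range(len(acceptor.body) - L, len(acceptor.body) - 1))
    if n_sub > len(candidates):
        raise ValueError("identity target needs more substitutions than positions")
    chosen = rng.choice(len(candidates), size=n_sub, replace=False)
    for idx in sorted(int(i) for i in chosen):
        p = candidates[idx]
        choices = _BASES.replace(acceptor.body[p], "")
        acceptor.body[p] = choices[rng.integers(0, 3)]

    # force divergence just beyond the block so its length is maximal
    if donor_boundary_base is not None and 0 <= boundary < len(acceptor.body):
        if acceptor.body[boundary] == donor_boundary_base:
            choices = _BASES.replace(donor_boundary_base, "")
            acceptor.body[boundary] = choices[rng.integers(0, 3)]

    # protect both sides of the block from later repair passes
    if spec.end == "5'":
        span_d = span_a = (0, L)
    else:
        span_d = (len(donor.body) - L, len(donor.body))
        span_a = (len(acceptor.body) - L, len(acceptor.body))
    donor.protected.update(range(*span_d))
    acceptor.protected.update(range(*span_a))

    realized = sum(
        1
        for x, y in zip(
            donor.body[span_d[0] : span_d[1]],
            acceptor.body[span_a[0] : span_a[1]],
        )
        if x == y
    ) / L
    truth.planted_blocks.append(
        {
            "seg_a": donor.id, "seg_b": acceptor.id, "end": spec.end,
            "length": L, "identity": realized,
            "span_a": list(span_d), "span_b": list(span_a),
        }
    )


def simulate(cfg: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate a virus set plus decoys; see the module docstring."""
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    library = _cassette_library(cfg, rng)
    cassette_names = list(library)

    n_viruses = int(rng.integers(cfg.n_viruses[0], cfg.n_viruses[1] + 1))
    segs: list[_Seg] = []
    block_trio: tuple[str, str, str] | None = None

    for v in range(n_viruses):
        virus = f"virus{v + 1}"
        motif = _make_motif(cfg, rng)
        truth.virus_motifs[virus] = motif
        n_seg = int(
            rng.integers(cfg.segments_per_virus[0], cfg.segments_per_virus[1] + 1)
        )
        plant_trio = v == 0 and bool(cfg.shared_block_specs) and n_seg >= 5
        n_regular = n_seg - 3 if plant_trio else n_seg

        # per-virus mutated copies of the shared cassettes
        virus_cassettes = {
            name: _mutate_protein(rng, prot, cfg.cassette_divergence)
            for name, prot in library.items()
        }

        for s in range(n_regular):
            seg_id = f"{virus}.s{s + 1:02d}"
            if s < len(cassette_names):
                klass = cassette_names[s]
                protein = virus_cassettes[klass]
            else:
                klass = f"orphan_{virus}_{s + 1}"
                protein = _rand_protein(
                    rng, int(rng.integers(80, 201))
                )
            target_len = int(
                rng.integers(cfg.segment_length[0], cfg.segment_length[1] + 1)
            )
            seg = _build_segment(seg_id, virus, motif, protein, klass,
                                 target_len, cfg, rng)
            segs.append(seg)
            truth.membership[seg.id] = virus
            truth.segment_class[seg.id] = klass
            truth.planted_orfs[seg.id] = {
                "start": seg.orf[0], "end": seg.orf[1],
                "frame": seg.orf[2], "rank": 1,
            }
            if s == 0:
                truth.anchors.append(seg.id)

        if plant_trio:
            # three extra segments mirror the S8/S9/S10-like block trio: a
            # donor whose 3' region is ORF-free, and a pair whose identical
            # 5' region carries an identical short ORF
            lo = max(cfg.segment_length[0], 1300)
            hi = max(cfg.segment_length[1], lo + 1)
            a_id = f"{virus}.s{n_seg - 2:02d}"
            b_id = f"{virus}.s{n_seg - 1:02d}"
            c_id = f"{virus}.s{n_seg:02d}"
            donor_protein = _rand_protein(rng, int(rng.integers(100, 151)))
            # target length forces a long ORF-free 3' UTR on the donor
            a_len = (
                cfg.terminal_motif_length + 60 + (len(donor_protein) + 1) * 3
                + int(rng.integers(500, 900))
            )
            seg_a = _build_segment(
                a_id, virus, motif, donor_protein, f"orphan_{virus}_sA",
                a_len, cfg, rng,
            )
            pair_protein = _rand_protein(rng, 120)
            seg_b = _build_segment(
                b_id, virus, motif, pair_protein, f"orphan_{virus}_pair",
                int(rng.integers(lo, hi + 1)), cfg, rng,
            )
            if seg_b.orf[1] > 790:
                raise RuntimeError("pair ORF does not fit inside the 5' block")
            seg_c = _build_segment(
                c_id, virus, motif, None, f"orphan_{virus}_cbody",
                int(rng.integers(lo, hi + 1)), cfg, rng,
            )
            segs.extend([seg_a, seg_b, seg_c])
            for sid, seg in ((a_id, seg_a), (b_id, seg_b), (c_id, seg_c)):
                truth.membership[sid] = virus
                truth.segment_class[sid] = seg.klass
            for sid, seg in ((a_id, seg_a), (b_id, seg_b)):
                truth.planted_orfs[sid] = {
                    "start": seg.orf[0], "end": seg.orf[1],
                    "frame": seg.orf[2], "rank": 1,
                }
            block_trio = (a_id, b_id, c_id)

    if block_trio is not None:
        a_id, b_id, c_id = block_trio
        for (end, length, identity), (donor, acceptor) in zip(
            cfg.shared_block_specs,
            ((b_id, c_id), (a_id, c_id), (c_id, b_id)),
        ):
            plant_shared_blocks(
                segs, truth,
                SharedBlockSpec(donor=donor, acceptor=acceptor, end=end,
                                length=length, identity=identity),
                rng, repeat_unit=cfg.repeat_unit,
            )
        by_id = {s.id: s for s in segs}
        for sid in (b_id, c_id):
            _repair_spurious_orfs(by_id[sid], cfg, rng)

    # duplicated segments: near-copies, class preserved
    base_by_virus: dict[str, list[_Seg]] = {}
    for seg in segs:
        base_by_virus.setdefault(seg.virus, []).append(seg)
    duplicates: list[_Seg] = []
    trio_ids = set(block_trio) if block_trio else set()
    for virus, members in base_by_virus.items():
        eligible = [
            m for m in members
            if m.id not in trio_ids and m.id not in truth.anchors
        ]
        n_dup = int(
            rng.integers(cfg.n_duplicated_segments[0],
                         cfg.n_duplicated_segments[1] + 1)
        )
        n_dup = min(n_dup, len(eligible))
        picks = rng.choice(len(eligible), size=n_dup, replace=False)
        for idx in sorted(int(i) for i in picks):
            src = eligible[idx]
            dup = _Seg(
                id=src.id + "d", virus=virus, body=list(src.body),
                tail=int(rng.integers(cfg.polyA_length[0], cfg.polyA_length[1] + 1)),
                klass=src.klass, orf=src.orf, protected=set(src.protected),
            )
            cds = set(range(src.orf[0], src.orf[1])) if src.orf else set()
            guard = set(range(src.orf[0] - 3, src.orf[0])) if src.orf else set()
            # non-coding positions: free substitutions
            for p in range(len(dup.body)):
                if p in cds or p in guard:
                    continue
                if rng.random() < cfg.duplicate_divergence:
                    choices = _BASES.replace(dup.body[p], "")
                    dup.body[p] = choices[rng.integers(0, 3)]
            # coding positions: codon-safe substitutions (no stops, ATG and
            # terminal stop kept)
            if src.orf is not None:
                for cs in range(src.orf[0] + 3, src.orf[1] - 3, 3):
                    for k in range(3):
                        if rng.random() < cfg.duplicate_divergence:
                            codon = dup.body[cs : cs + 3]
                            choices = _BASES.replace(codon[k], "")
                            new = list(codon)
                            new[k] = choices[rng.integers(0, 3)]
                            if translate("".join(new)) != "*":
                                dup.body[cs : cs + 3] = new
            _repair_spurious_orfs(dup, cfg, rng)
            duplicates.append(dup)
            truth.membership[dup.id] = virus
            truth.segment_class[dup.id] = dup.klass
            truth.planted_orfs[dup.id] = {
                "start": dup.orf[0], "end": dup.orf[1],
                "frame": dup.orf[2], "rank": 1,
            }
    segs.extend(duplicates)

    # realized tandem-repeat copies, recomputed from final motif regions
    for seg in segs:
        window = "".join(seg.body[: cfg.terminal_motif_length])
        hit = max_tandem_repeat(window, cfg.repeat_unit)
        truth.planted_repeats[seg.id] = hit.copies if hit else 0

    # decoys: host-like contigs with a tail but no motif and no cassette
    n_decoys = (
        cfg.n_decoys
        if cfg.n_decoys is not None
        else round(cfg.decoy_fraction * len(segs))
    )
    records: list[SequenceRecord] = []
    for seg in segs:
        seq = "".join(seg.body) + "A" * seg.tail
        records.append(SequenceRecord(id=seg.id, residues=seq,
                                      moltype="nucleotide"))
    for k in range(n_decoys):
        decoy_id = f"decoy.{k + 1:02d}"
        n = int(rng.integers(cfg.decoy_length[0], cfg.decoy_length[1] + 1))
        tail = int(rng.integers(cfg.polyA_length[0], cfg.polyA_length[1] + 1))
        records.append(
            SequenceRecord(id=decoy_id, residues=_rand_nt(rng, n) + "A" * tail,
                           moltype="nucleotide")
        )
        truth.membership[decoy_id] = "decoy"

    # emission strand (every contig carries a poly(A) tail, so orientation
    # is recoverable for decoys too)
    for rec in records:
        strand = "-" if rng.random() < cfg.reverse_fraction else "+"
        truth.orientation[rec.id] = strand
        if strand == "-":
            rec.residues = reverse_complement(rec.residues)

    # k-mer coverage: negative binomial, high for segments, low for decoys
    for rec in records:
        if truth.membership[rec.id] == "decoy":
            mean, size = cfg.coverage_decoy_mean, 5.0
        else:
            mean, size = cfg.coverage_segment_mean, 30.0
        p = size / (size + mean)
        truth.coverage[rec.id] = float(rng.negative_binomial(size, p))

    records.sort(key=lambda r: r.id)
    return records, truth


def emit(
    records: list[SequenceRecord],
    truth: GroundTruth,
    outdir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write ``contigs.fasta``, ``coverage.tsv`` and ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.is_file()]
    if existing and not force:
        raise FileExistsError(
            f"{outdir} is not empty (pass force=True to overwrite)"
        )
    paths = {
        "contigs": outdir / "contigs.fasta",
        "coverage": outdir / "coverage.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(records, paths["contigs"])
    with open(paths["coverage"], "w") as fh:
        fh.write("contig_id\tkmer_coverage\n")
        for rec in records:
            fh.write(f"{rec.id}\t{truth.coverage[rec.id]:.1f}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
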