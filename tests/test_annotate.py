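"""ORF finding, peptide evidence, motif scanning and protein mass."""

import re

import pytest

from vivipart.annotate import (
    MotifDefinition,
    OrfRecord,
    PeptideEvidence,
    find_orfs,
    load_motif_catalog,
    molecular_weight,
    peptide_coverage,
    predict_cleavage,
    refine_start,
    scan_motif,
)
from vivipart.core_io import Interval, translate

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq: str, min_aa: int):
    """Independent codon walk: every maximal AUG..stop span per frame."""
    expected = set()
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        starts = [i for i, c in enumerate(codons) if c == "ATG"]
        stops = [i for i, c in enumerate(codons) if c in _STOPS]
        for s in starts:
            nxt = [t for t in stops if t > s]
            if not nxt:
                continue
            t = nxt[0]
            # maximal: no earlier ATG reaches this stop without a stop between
            prior_stops = [x for x in stops if x < s]
            lo = prior_stops[-1] + 1 if prior_stops else 0
            if any(codons[i] == "ATG" for i in range(lo, s)):
                continue
            if t - s >= min_aa:
                expected.add((frame + 3 * s, frame + 3 * (t + 1), frame))
    return expected


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGAAATAA", min_aa=1)
        assert len(orfs) == 1 and orfs[0].protein == "MK"
        assert (orfs[0].nt_span.start, orfs[0].nt_span.end) == (0, 9)

    def test_no_atg_no_orfs(self):
        assert find_orfs("AAACCCGGGTTT" * 10, min_aa=1) == []

    def test_retranslation_invariant(self, rng):
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
            for orf in find_orfs(seq, min_aa=20):
                span = seq[orf.nt_span.start : orf.nt_span.end]
                assert translate(span) == orf.protein + "*"

    def test_brute_force_oracle_500_random_2kb(self, rng):
        for _ in range(500):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
            got = {
                (o.nt_span.start, o.nt_span.end, o.frame)
                for o in find_orfs(seq, min_aa=30)
            }
            assert got == brute_force_orfs(seq, 30)

    def test_sorted_longest_first(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        orfs = find_orfs(seq, min_aa=10)
        lengths = [len(o.protein) for o in orfs]
        assert lengths == sorted(lengths, reverse=True)


class TestPeptideCoverage:
    def test_first_match_position(self):
        cov = peptide_coverage("MABCDEFGHIK", [PeptideEvidence("CDEFGH")])
        assert cov.first_match_position == 4
        assert cov.uncovered_n_terminal == 3

    def test_tiling_covers_everything(self):
        prot = "MKLFGATNDE"
        cov = peptide_coverage(prot, [PeptideEvidence("MKLFGA"),
                                      PeptideEvidence("GATNDE")])
        assert cov.uncovered_n_terminal == 0
        assert [(c.start, c.end) for c in cov.covered] == [(0, 10)]

    def test_il_collapsed_matching(self):
        # I and L are indistinguishable by mass spectrometry
        cov = peptide_coverage("MKILVFGG", [PeptideEvidence("KLLVFG")])
        assert cov.first_match_position == 2

    def test_unmatched_listed_not_raised(self):
        cov = peptide_coverage("MKLFGATNDE", [PeptideEvidence("WWWWWW")])
        assert cov.unmatched == ["WWWWWW"]
        assert cov.first_match_position is None

    def test_interval_union_oracle(self, rng):
        """Union of random tryptic-like fragments equals a position-set oracle."""
        prot = "".join("ACDEFGHKMNPQRSTVWY"[i] for i in rng.integers(0, 18, 200))
        peptides, expected = [], set()
        for _ in range(20):
            s = int(rng.integers(0, 190))
            ln = int(rng.integers(6, 11))
            peptides.append(PeptideEvidence(prot[s : s + ln]))
        cov = peptide_coverage(prot, peptides)
        # oracle: all positions covered by any exact occurrence
        for pep in peptides:
            for m in re.finditer(f"(?={re.escape(pep.peptide)})", prot):
                expected |= set(range(m.start(), m.start() + len(pep.peptide)))
        got = set()
        for iv in cov.covered:
            got |= set(range(iv.start, iv.end))
        assert got == expected
        # merged intervals are disjoint and sorted
        for a, b in zip(cov.covered, cov.covered[1:]):
            assert a.end < b.start


class TestRefineStart:
    def _orf(self, protein):
        return OrfRecord("c", Interval(0, 3 * (len(protein) + 1)), 0, protein)

    def test_full_coverage_keeps_rank_one(self):
        prot = "MKLFGATNDEMWQRST" + "K" * 20
        cov = peptide_coverage(prot, [PeptideEvidence(prot[:10], n_terminal_acetyl=True)])
        rank, why = refine_start(self._orf(prot), cov)
        assert rank == 1 and "rank-1" in why

    def test_acetyl_peptide_selects_second_aug(self):
        # rank-2 Met at 1-based position 12; acetylated peptide starts at 13
        # (Met cleaved), first peptide match also at 13
        prot = "MAAAAAAAAAA" + "M" + "SSSSSSSSKLF" + "G" * 30
        acetyl = PeptideEvidence(prot[12:20], n_terminal_acetyl=True)
        cov = peptide_coverage(prot, [acetyl])
        assert cov.first_match_position == 13
        rank, why = refine_start(self._orf(prot), cov)
        assert rank == 2 and "Met-cleaved" in why

    def test_met_retained_policy_accepted(self):
        prot = "MAAAAAAAAAA" + "MSSSSSSSKLF" + "G" * 30
        acetyl = PeptideEvidence(prot[11:19], n_terminal_acetyl=True)
        cov = peptide_coverage(prot, [acetyl])
        rank, why = refine_start(self._orf(prot), cov)
        assert rank == 2 and "Met-retained" in why

    def test_no_peptides_flagged_unrefined(self):
        rank, why = refine_start(self._orf("M" + "K" * 30), peptide_coverage("M" + "K" * 30, []))
        assert rank == 1 and "unrefined" in why


class TestScanMotif:
    def brute_force(self, protein, motif):
        hits = []

        def matches(block, pos):
            if pos + len(block) > len(protein):
                return False
            return all(
                c == "x" or protein[pos + k] in c for k, c in enumerate(block)
            )

        n = len(protein)
        for p0 in range(n):
            if not matches(motif.blocks[0], p0):
                continue
            e0 = p0 + len(motif.blocks[0])
            for p1 in range(n):
                if not matches(motif.blocks[1], p1):
                    continue
                g1 = p1 - e0
                if not motif.spacers[0][0] <= g1 <= motif.spacers[0][1]:
                    continue
                e1 = p1 + len(motif.blocks[1])
                for p2 in range(n):
                    if not matches(motif.blocks[2], p2):
                        continue
                    g2 = p2 - e1
                    if motif.spacers[1][0] <= g2 <= motif.spacers[1][1]:
                        hits.append((p0, p1, p2))
        return sorted(hits)

    def test_hand_placed_pcpro_anchors(self):
        catalog = load_motif_catalog()
        pcpro = catalog["PCPro"]
        protein = "M" * 5 + "GACY" + "A" * 20 + "H" + "A" * 30 + "VGG" + "M" * 5
        hits = scan_motif(protein, pcpro)
        assert len(hits) == 1
        assert hits[0].block_starts == (5, 29, 60)
        assert hits[0].matched == ("GACY", "H", "VGG")

    def test_empty_protein(self):
        catalog = load_motif_catalog()
        assert scan_motif("", catalog["PCPro"]) == []

    def test_exhaustive_placement_oracle(self, rng):
        motif = MotifDefinition(
            name="toy",
            blocks=(("G", "x", "C"), ("HR",), ("VILM", "G")),
            spacers=((2, 30), (2, 40)),
        )
        for _ in range(60):
            protein = "".join(
                "ACGHRVILMX"[i] for i in rng.integers(0, 10, rng.integers(20, 200))
            )
            got = sorted(h.block_starts for h in scan_motif(protein, motif))
            assert got == self.brute_force(protein, motif)

    def test_catalog_triad_spacing_matches_exemplar(self):
        """His/Asp/Ser triad at the exemplar gaps (42, 74) is matched."""
        catalog = load_motif_catalog()
        protein = "A" * 10 + "H" + "A" * 42 + "D" + "A" * 74 + "S" + "A" * 10
        hits = scan_motif(protein, catalog["CSPro"])
        assert any(h.block_starts == (10, 53, 128) for h in hits)


class TestCleavage:
    def test_single_site(self):
        assert predict_cleavage("AVGGA") == [3]

    def test_no_site(self):
        assert predict_cleavage("AVGA") == []

    def test_regex_oracle_1000_random(self, rng):
        for _ in range(1000):
            prot = "".join("AVILMGKW"[i] for i in rng.integers(0, 8, 60))
            expected = [
                m.start() + 2 for m in re.finditer(r"(?=[VILM]GG)", prot)
            ]
            assert predict_cleavage(prot) == expected


class TestMolecularWeight:
    def test_glycine(self):
        assert abs(molecular_weight("G") - 0.07507) < 1e-4  # 75.07 Da

    def test_additivity_minus_water(self):
        from Bio.SeqUtils import molecular_weight as bio_mw

        full = bio_mw("ACDE", seq_type="protein")
        parts = bio_mw("AC", seq_type="protein") + bio_mw("DE", seq_type="protein")
        water = 18.0153
        assert abs(parts - water - full) < 0.01

    def test_capsid_like_mass_band(self, rng):
        """A ~270-aa capsid-like protein lands in the 25-35 kDa band."""
        prot = "M" + "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 269)
        )
        assert 25 <= molecular_weight(prot) <= 35

    def test_ambiguous_residue_rejected_with_positions(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            molecular_weight("AXG")
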