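"""Greedy homolog clustering, genome-content matrix, PSSM search."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from vivipart.core_io import SequenceRecord
from vivipart.grouping import assign_genomes
from vivipart.homology_clusters import (
    build_profile,
    content_matrix,
    detect_duplications,
    greedy_cluster,
    profile_search,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def prot(seq, pid="p"):
    return SequenceRecord(id=pid, residues=seq, moltype="protein")


def rand_prot(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, n))


@pytest.fixture(scope="module")
def pipeline1(sim1, sim1_plus):
    """Seed-1 grouping plus longest-ORF proteins of all bundle members."""
    from vivipart.annotate import find_orfs

    records, truth = sim1
    decisions, bundles, _ = assign_genomes(records, truth.coverage, truth.anchors)
    proteins = []
    for b in bundles:
        for m in b.members:
            orfs = find_orfs(sim1_plus[m], min_aa=50)
            proteins.append(prot(orfs[0].protein, m))
    return bundles, proteins


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self, rng):
        p = rand_prot(rng, 120)
        ca = greedy_cluster([prot(p, "a"), prot(p, "b")])
        assert len(set(ca.assignment.values())) == 1

    def test_random_proteins_stay_apart(self, rng):
        """Random 200-aa proteins sit far below the 0.30 admission identity."""
        for _ in range(30):
            ca = greedy_cluster([prot(rand_prot(rng, 200), "a"),
                                 prot(rand_prot(rng, 200), "b")])
            assert len(set(ca.assignment.values())) == 2

    def test_members_satisfy_admission_post_hoc(self, pipeline1):
        _, proteins = pipeline1
        ca = greedy_cluster(proteins)
        for pid in ca.assignment:
            assert ca.identity[pid] >= 0.30
            assert ca.coverage[pid] >= 0.50

    def test_simulator_cassettes_recovered(self, sim1, pipeline1):
        records, truth = sim1
        _, proteins = pipeline1
        ca = greedy_cluster(proteins)
        t_labels = [truth.segment_class[p.id] for p in proteins]
        c_labels = [ca.assignment[p.id] for p in proteins]
        assert adjusted_rand_score(t_labels, c_labels) == 1.0

    def test_order_invariance_after_sort(self, rng):
        base = rand_prot(rng, 150)
        fam = [prot(base, "a"), prot(base[:120], "b"), prot(rand_prot(rng, 100), "c")]
        ca1 = greedy_cluster(fam)
        ca2 = greedy_cluster(list(reversed(fam)))
        assert ca1.assignment == ca2.assignment


class TestContentMatrix:
    def test_disjoint_cassettes_permutation_structure(self, rng):
        from vivipart.grouping import VirusBundle
        from vivipart.terminus import TerminalProfile

        def bundle(vid, members):
            profile = TerminalProfile(virus_id=vid, window_length=4,
                                      consensus="ACGT",
                                      per_column_conservation=[1.0] * 4,
                                      repeat={})
            return VirusBundle(virus_id=vid, members=members, profile=profile,
                               anchors=members[:1])

        proteins = []
        bundles = []
        for v in range(3):
            members = [f"v{v}.s{s}" for s in range(3)]
            bundles.append(bundle(f"virus{v}", members))
            for m in members:
                proteins.append(prot(rand_prot(rng, 120), m))
        ca = greedy_cluster(proteins)
        matrix = content_matrix(bundles, ca)
        assert matrix.values.sum() == 9
        assert (matrix.sum(axis=1) == 3).all()  # row sums = clustered proteins
        assert (matrix.values <= 1).all()  # disjoint cassettes, no copies

    def test_unknown_protein_error(self, pipeline1):
        bundles, proteins = pipeline1
        ca = greedy_cluster(proteins + [prot("M" * 80, "stranger")])
        with pytest.raises(ValueError, match="stranger"):
            content_matrix(bundles, ca)


class TestDuplications:
    def test_all_ones_matrix_empty(self):
        import pandas as pd

        matrix = pd.DataFrame(1, index=["v1"], columns=["c1", "c2"])
        assert detect_duplications(matrix) == []

    def test_triple_copy_event(self):
        import pandas as pd

        matrix = pd.DataFrame([[3, 1]], index=["v1"], columns=["c1", "c2"])
        events = detect_duplications(matrix)
        assert len(events) == 1 and events[0].count == 3

    def test_simulator_duplications_match_truth(self, sim1, pipeline1):
        records, truth = sim1
        bundles, proteins = pipeline1
        ca = greedy_cluster(proteins)
        matrix = content_matrix(bundles, ca)
        events = detect_duplications(matrix, ca, bundles)
        got = {e.members for e in events}
        expected = set()
        for (virus, klass), _count in truth.duplication_events().items():
            expected.add(tuple(sorted(
                c for c, v in truth.membership.items()
                if v == virus and truth.segment_class.get(c) == klass
            )))
        assert got == expected


class TestProfiles:
    def test_two_identical_members_hand_calculation(self):
        p = "MKLF" * 10
        profile = build_profile([prot(p, "a"), prot(p, "b")], "c1")
        # count 2 of 2 -> (2+1)/(2+20) / 0.05, everything else (0+1)/22/0.05
        top = math.log2((3 / 22) / 0.05)
        rest = math.log2((1 / 22) / 0.05)
        assert profile.length == len(p)
        for scores in profile.scores:
            assert max(scores) == pytest.approx(top)
            assert sorted(set(np.round(scores, 9)))[0] == pytest.approx(rest)

    def test_profile_not_longer_than_alignment(self, rng):
        members = [prot(rand_prot(rng, 80), "a"), prot(rand_prot(rng, 70), "b")]
        profile = build_profile(members)
        assert profile.length <= 150

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            build_profile([prot("MKLF" * 10, "a")])

    def test_member_hit_recovered_top_score(self, rng):
        cassette = rand_prot(rng, 80)
        profile = build_profile([prot(cassette, "a"), prot(cassette, "b")], "c1")
        # embed the exact cassette in a contig, plus-strand frame 1
        from vivipart.synthetic_data import _reverse_translate

        rng2 = np.random.default_rng(7)
        cds = _reverse_translate(rng2, cassette)
        contig = SequenceRecord(
            "c", "G" + cds + "".join("ACGT"[i] for i in rng.integers(0, 4, 200)),
            moltype="nucleotide",
        )
        hits = profile_search([contig], profile, min_bits=50)
        assert hits and hits[0].frame == 1
        # top hit covers the embedded cassette exactly
        assert (hits[0].nt_span.start, hits[0].nt_span.end) == (1, 1 + 240)
        assert hits[0].score >= 50

    def test_decoys_score_below_threshold(self, rng):
        cassette = rand_prot(rng, 100)
        profile = build_profile([prot(cassette, "a"), prot(cassette, "b")], "c1")
        for _ in range(20):
            decoy = SequenceRecord(
                "d", "".join("ACGT"[i] for i in rng.integers(0, 4, 2000)),
                moltype="nucleotide",
            )
            assert profile_search([decoy], profile, min_bits=50) == []

    def test_placement_equals_bruteforce_scan(self, rng):
        cassette = rand_prot(rng, 40)
        profile = build_profile([prot(cassette, "a"), prot(cassette, "b")], "c1")
        protein = rand_prot(rng, 200) + cassette + rand_prot(rng, 100)
        window_scores = profile.score_protein(protein)
        # brute force: score every offset by direct summation
        for off in range(0, len(protein) - profile.length + 1, 17):
            s = sum(
                profile.scores[j][AA20.index(protein[off + j])]
                for j in range(profile.length)
            )
            assert window_scores[off] == pytest.approx(s)
        assert int(np.argmax(window_scores)) == 200

    def test_point_mutant_never_outscores_member(self, rng):
        """Log-odds monotonicity: mutating one residue of a member cannot
        increase its profile score."""
        cassette = rand_prot(rng, 60)
        profile = build_profile([prot(cassette, "a"), prot(cassette, "b")], "c1")
        base = profile.score_protein(cassette)[0]
        for _ in range(30):
            pos = int(rng.integers(0, 60))
            mutant = list(cassette)
            mutant[pos] = AA20[(AA20.index(mutant[pos]) + 1 + int(rng.integers(0, 19))) % 20]
            if "".join(mutant) == cassette:
                continue
            assert profile.score_protein("".join(mutant))[0] <= base
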