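# Methods

This note documents the models, parameter choices and numerical decisions
behind `vivipart`, and states plainly what the synthetic benchmark does and
does not show.

## Coordinate and alphabet conventions

All coordinates are 0-based half-open on the plus strand of the stored
sequence; reverse-strand features exist only after explicit
reverse-complementation. Rendered TSV reports use 1-based inclusive
coordinates and say so in a header line. `U` is normalized to `T` on
ingestion (viral RNA genomes are deposited in the DNA alphabet); IUPAC
ambiguity codes are retained and never randomly resolved; codons containing
an ambiguity translate to `X`.

## Alignment

One affine-gap global alignment underlies terminal comparison, clustering
and consensus building. Nucleotide scoring defaults to match +1,
mismatch −1, gap open −4, gap extend −1: the heavy opening cost favors the
contiguous matches that genuine terminal homology produces over scattered
identity in random sequence. Protein comparisons use BLOSUM62 with
−11/−1 gaps. A gap of length L costs `open + (L−1)·extend`. The dynamic
program is Biopython's `PairwiseAligner` (optimal, deterministic first
traceback); optimality is cross-checked in the tests against exhaustive
enumeration of every alignment path for short strings. Identity is
matches/columns; the `exclude_end_gaps` mode drops terminal columns gapped
in either row so assembly-truncated segments are not penalized — it is the
mode used for clustering admission.

The multiple alignment is a center-star MSA: the center maximizes the
summed pairwise score; other rows merge against it under "once a gap,
always a gap". For the ~80–100 nt terminal windows and within-cluster
proteins this package aligns, star MSA is accurate and exactly
reproducible; it is not intended for deep or twilight-zone alignments.

## Terminal signals

* **Poly(A) trimming** removes the maximal *exact* terminal A-run when it
  is ≥ 8 nt. Exactness matters: a mismatch-tolerant rule could eat genuine
  3′ sequence that the shared-block analyses depend on. A consequence is
  that an A immediately preceding the tail is indistinguishable from the
  tail; windows anchored at the trimmed 3′ end are defined with respect to
  this rule.
* **Tandem repeats** are exact-match: a degenerate copy (e.g. `CAAAAA`)
  terminates the tandem, matching how a strict pentamer repeat is read off
  an alignment. The detector equals a brute-force all-starts scan.
* **Conserved terminal length** is the largest window length L (multiple of
  5 nt) whose mean pairwise 5′-window identity is ≥ 0.9. The 5-nt step
  acknowledges that single-nucleotide resolution is noise at a few percent
  terminal divergence. On the default simulations the estimate is 80–90 nt
  for a planted 80-nt motif.

## Grouping

Anchor contigs (marker-bearing, e.g. RdRP) are single-linkage clustered on
5′ 100-nt window identity at 0.70; orphans are assigned to the bundle
consensus they match at ≥ 0.70 with a ≥ 0.05 lead over the runner-up.
Unrelated random 100-nt termini align at ≈ 0.4–0.5 identity under the
default scoring and never approach 0.70, while same-virus termini at ≤ 5 %
per-site divergence score ≈ 0.85+ over the 100-nt window (the window spans
the 80-nt motif plus ~20 nt of unrelated sequence); the margin exists for
samples co-infected by related viruses. The coverage filter (depth ≥ 0.1 ×
median anchor depth) is advisory: it partitions and annotates, it never
deletes, because the in-silico criterion cannot be the ultimate arbiter the
way targeted RT-PCR validation is — the artifact must keep every decision
auditable. Contigs are processed in lexicographic id order; repeated runs
are byte-identical.

Orientation: the strand whose 3′ end carries the poly(A) run wins; if both
or neither qualify, the longer longest-ORF strand wins; remaining ties keep
the input strand, flagged ambiguous.

## Annotation

ORFs are all maximal AUG→stop spans in the three plus-strand frames
(minimum 50 aa by default); internal AUGs are start-codon candidates of the
same ORF (rank 1 = 5′-most). Start-site refinement uses mass-spectrometry
evidence computed against the rank-1 protein: among AUGs of rank 1–3, the
largest rank whose first residue coincides exactly with an N-terminally
acetylated peptide is proposed; both Met-retained and Met-cleaved N-termini
are accepted because acetylation evidence does not resolve initiator-Met
processing. Peptide matching is exact with I/L collapsed (isobaric).

Motifs are ordered residue-class blocks with bounded spacers, shipped as an
editable YAML catalog. The contents are the field's diagnostic signatures;
the spacer bounds are chosen to bracket the exemplar coordinates (the
serine-protease triad at His/Asp/Ser with gaps 42 and 74 sits inside the
20–80 and 40–120 bounds). The scanner enumerates every placement,
overlapping hits included, and equals a brute-force enumeration on proteins
up to 200 aa. Protein mass is the isotope-averaged sum (Biopython) in kDa.

## Shared blocks

Near-identical regions between segments of one virus are found by exact
15-mer seeding and greedy ungapped X-drop extension (drop 10 under +1/−2),
with same-diagonal extensions merged, on poly(A)-trimmed sequences; blocks
are reported at ≥ 50 nt and ≥ 0.8 identity and classified 5′-terminal,
3′-terminal or internal. k = 15 keeps chance seeds between unrelated
multi-kb segments negligible. Identity-1.0 blocks are recovered at their
exact planted length; for blocks *below* identity 1, seed-and-extend
endpoints are heuristic (a 101-nt block at 90 % often contains no exact
15-mer), so exact statements about terminal blocks use the dedicated
primitives instead: `longest_common_prefix/suffix` for identical regions
and `terminal_identity` (ungapped, anchored at the terminus; the gapped
value is reported alongside) for near-identical ones. Reported block
identities always recompute exactly from the reported coordinates.

## Homolog clusters and profiles

Greedy longest-first clustering with admission at ≥ 0.30 identity
(exclude-end-gaps) and ≥ 0.50 bidirectional coverage — conventional
easy-cluster-style parameters. The genome-content matrix counts member
proteins per virus per cluster; any cell ≥ 2 is a duplicated segment, the
operational definition of within-genome duplication. The per-cluster
profile is a PSSM: star MSA, gap-majority columns dropped, per-column
log-odds `log2(((count+1)/(n+20))/0.05)` (one pseudocount per residue,
uniform background), searched ungapped over three-frame translations with
a 50-bit default threshold. The PSSM is a deliberate fidelity trade-off
against a full profile HMM (no insert/delete states): segment recovery in
this setting concerns strong within-family hits, and the ungapped model is
exhaustively verifiable. Unknown residues score 0.

## Trees

p-distances over columns ungapped in both rows (optional Poisson
correction); canonical neighbor joining with lexicographic tie-breaking
(deterministic) and negative branch-length estimates clamped at zero — NJ
is exact on additive matrices, which the tests verify to 1e-9 on random
8-leaf trees; midpoint rooting places the root on the longest leaf-to-leaf
path and provably minimizes tree height over all edge rootings (verified
against an exhaustive oracle). Duplicate-segment clades are tested two
ways: `is_monophyletic` on a rooted tree, and `is_split` on the unrooted
NJ tree (clade under some rooting outside the set). The unrooted reading is
the robust one for trees of a handful of leaves: a duplicate's long pendant
branch can attract the midpoint root into the pair's cherry, a rooting
artifact that does not change the topology. Model-based likelihood
inference and branch support are deliberately out of scope.

## The synthetic-data generator

The generator emulates a multipartite virus discovery scenario:

* 3–5 viruses with 5–12 segments of 1,000–3,700 nt (the observed span of
  vivivirid segment lengths), each segment carrying an independently
  mutated copy (3 % per site) of its virus's 80-nt terminal motif with a
  (CAAAA)₇₋₈ repeat, one plus-strand ORF, a 3′ UTR and a 15–40 nt poly(A)
  tail.
* A library of 8 protein cassettes (80–300 aa) shared across viruses at
  5 % per-residue divergence models the conserved core segments; segments
  beyond the library carry virus-unique orphan proteins, mirroring the
  orphan segments real viviviruses show.
* Per virus, 0–2 segments are duplicated as near-copies (2 % per site,
  codon-safe inside the CDS).
* In the first virus, three designated segments carry the planted
  recombination signature: an identical 800-nt 5′ prefix between two
  segments (including an identical 120-aa ORF), an identical 263-nt 3′
  suffix with a third, and a 101-nt 3′ block at target identity 0.90 —
  realized as exactly `round((1−identity)·length)` substitutions, so the
  realized identity (91/101) recomputes exactly. The position just beyond
  each planted block is forced to differ so block lengths are maximal.
* ~20 % decoy host-like contigs with segment-like lengths and GC, a
  poly(A) tail but no motif and no cassette; coverage is negative binomial
  (segments mean 200, dispersion 30; decoys mean 5, dispersion 5), so only
  the motif and coverage signals separate decoys from segments.
* Roughly half the contigs are emitted reverse-complemented; the truth
  records the planted strand.

Two deterministic construction details keep the ground truth exact. Chance
plus-strand ORFs long enough to rival a planted ORF (within a 10-aa
margin) are repaired away by inserting a stop codon at unprotected
positions or, where the offender is buried in planted coding sequence, by
synonymous recoding; a protected-position mask guarantees planted motifs,
ORFs and blocks are never touched. And no segment body ends in `A`, so the
exact-run poly(A) trim boundary is unambiguous and 3′-anchored windows
recompute exactly.

All randomness flows from one seeded generator; a fixed seed yields
byte-identical FASTA/TSV/JSON output.

**What the benchmark shows — and does not.** Recovery at adjusted Rand
index 1.0 over 20 seeds shows the procedure is correct and well-calibrated
under the stated conditions: substitution-only divergence, homopolymeric
tails, complete segments, one virus set per sample. Real assemblies add
indels and assembly errors in termini, truncated contigs, chimeras and
cross-sample strain mixtures; the thresholds are exposed in the config
precisely because those conditions will move them, and the coverage filter
stays advisory for the same reason.

## Problem sizes

The default test suite and the acceptance script run the full pipeline on
20 simulator seeds (≈ 40–60 contigs each) plus the oracle-equivalence
suites (500 × 2-kb ORF scans, 1,000 repeat scans, exhaustive alignment
enumeration for short strings, 8–12-leaf tree oracles); the whole suite
completes in well under a minute on one CPU. The spot checks against the
deposited 10-segment reference genome run only when the user supplies the
segment FASTA (`data/favvv1_segments.fasta`); no network access is ever
attempted.
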