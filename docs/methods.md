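# Methods

This note records the models, conventions, and numerical choices behind
`evescout`, and what the synthetic benchmark does and does not demonstrate.

## Coordinates and alphabets

All nucleotide coordinates are 1-based inclusive (GenBank/GFF3 convention)
so that screen output interleaves with public annotations. Nucleotide
records are restricted to {A,C,G,T,N}; other IUPAC ambiguity codes are
rejected rather than silently translated because the integrity checks
(internal stops, motif identity) require unambiguous codons. Translation
uses the standard genetic code only — the targets are nuclear nematode
loci. FASTA parsing is done in-package so that malformed input errors can
name the offending line.

## Homology seeding

The seeding step is an exact (non-heuristic) Smith–Waterman over all six
reading frames. Desk-scale assemblies make exactness affordable, and an
exact DP is directly testable against brute-force enumeration; a
seed-and-extend accelerator would be an optional extension. Defaults are
the community standards: BLOSUM62, gap open 11 / extend 1 (a gap of length
k costs `open + (k−1)·extend`), gapped Karlin–Altschul constants λ = 0.267,
K = 0.041.

E-values are **not** computed: they depend on the size of the database
searched and cannot be reproduced outside it. Loci are instead seeded by
bit score ≥ 50 and aligned length ≥ 80 residues. Same-contig, same-frame
hits separated by ≤ 1,000 nt merge into one locus, because an envelope
cassette may align in pieces.

The second-iteration PSSM uses per-column log-odds in half-bit units with
matrix-derived pseudocounts: the pseudocount distribution for a column is
`Σ_r f_r·P(a|r)` with `P(a|r) = p_a·2^(s_ar/2)`, so a single-row model at
large pseudocount weight recovers the background substitution scores —
a closed-form limit the tests assert. Columns with > 50% gaps are dropped.

The DP kernels (local and global Gotoh) are numba-compiled and operate on a
per-query-position score profile, so one code path serves plain queries,
PSSMs, and nucleotide repeat detection. Genome frames are scanned in
20,000-residue blocks with overlap 2×query-length to bound memory;
multiple hits per frame are extracted by iterative best-hit masking.

## Terminal repeats

The repeat pair is the best local alignment between the first and last
`flank_window` nucleotides of a locus, scored match +2 / mismatch −3 / gap
open −5 / extend −2, with identity = matches over aligned columns
(gap-inclusive — the conservative convention of common identity matrices;
under the mismatch-only convention values would be slightly higher).
Classification: **intact** at identity ≥ 95% and length ≥ 100 nt;
**degenerate** below the identity threshold; **truncated** when a
sub-minimum repeat abuts a contig end (within 20 nt); **solo** when a known
repeat sequence finds exactly one copy in the locus; **none** otherwise.
The 95%/100-nt defaults bracket the reported identity range of real
elements of this family while excluding microsatellite hits. Target-site
duplications are not required for a call.

Because the envelope cassette sits adjacent to the 3′ repeat while Gag
abuts the 5′ repeat, the locus window extends 8,000 nt to the element's 5′
side of the merged hits and 2,000 nt to the 3′ side (orientation follows
the hit frames), and the repeat search window is 3,000 nt. A symmetric
2,000-nt flank with a 1,500-nt search window cannot bridge a ~9-kb element
whose homology seed covers only the envelope third; these three defaults
were sized together so that window ⊇ flank + repeat for elements up to
~12 kb, and all are configurable.

## Polyprotein integrity

"No introns" is operationalized without splice-site modeling: the single
longest ATG→stop frame (ties: forward strand, then leftmost) must be
stop-free, reach ≥ 1,500 codons, and cover ≥ 80% of the inter-LTR
interior. The 1,500-codon floor is far below any credible complete
Gag-Pol-Env (~2,800 residues) but above every fragment a mid-ORF stop or
frameshift can leave. The polymerase-site tetrad Y-X-D-[D/N] is searched in
the middle third by default (Pol territory — full-length scanning is a
flag) to avoid chance tetrads in Gag/Env; the Gag/Pol boundary is anchored
150 residues upstream of the tetrad, a declared convention rather than a
domain model.

## Envelope architecture

The TM caller is a Kyte–Doolittle sliding mean (window 19, threshold 1.6,
minimum run 17, runs < 5 apart merged; termini use truncated windows). The
underlying study of this element family does not name its TM predictor;
these canonical settings are a declared substitute and are configurable.
Cleavage sites are approximated by cassette boundaries adjacent to TM
segments — the discriminating evidence is layout, not protease chemistry.
Signal-peptide prediction is out of scope.

Classification is deterministic and hit-order-independent:
phlebovirus-like iff (a) a G<sub>C</sub>-query hit occupies the C-terminal
portion (end within the last 20% of the protein), (b) a distinct upstream
G<sub>N</sub>-like region exists (its own TM ending within ±40 residues of
the G<sub>C</sub> hit start, or a G<sub>N</sub>-query hit), and (c) the
G<sub>C</sub> region carries exactly one TM, located within the last 60
residues. The G<sub>N</sub>/G<sub>C</sub> boundary is placed at the end of
the G<sub>N</sub> TM when one exists. Cassette-local residue numbering
(e.g. sequon positions) is anchored at the G<sub>C</sub> hit start, which
for a cognate query is the cassette start itself. A retrovirus-like call
requires a single C-terminal TM behind a heptad-bearing ectodomain (≥ 6 of
8 a/d positions hydrophobic over four heptads, any register) — a crude
coiled-coil proxy, sufficient to separate the architectures.

## Phylogeny

Alignment is guide-tree progressive: 3-mer Jaccard distances, NJ-style
guide joins, profile–profile global alignment under the same BLOSUM62/11/1
scoring (sum-of-pairs expected score; gaps contribute zero column mass).
Determinism is enforced by sorting taxa lexicographically, breaking
Q-criterion ties toward the lowest index pair, and orienting each merge by
smallest member id, so the alignment is invariant to input order.

Distances are Poisson-corrected, `d = −ln(1 − p)` over shared ungapped
columns (gapped columns excluded pairwise, not listwise, because RT
fragments differ in coverage); saturated pairs (p = 1) take a declared
maximum of 10 substitutions/site. Trees come from classic neighbor joining
(Studier–Keppler Q matrix, lowest-index tie-breaking, negative branch
estimates clamped to zero and logged); additive matrices are recovered
exactly, which the tests assert via patristic-matrix equality and zero
Robinson–Foulds distance on random binary trees. NJ stands in for maximum
likelihood deliberately: the testable claims are nearest-neighbor
relations, which are robust to method at these divergences; an ML backend
is an extension hook. Newick output serializes branch lengths with
round-trip float precision.

## The synthetic benchmark

The generator plants elements with the anatomy of the best-characterized
intact member of this family: 271-nt LTRs, a 2,828-residue polyprotein
(Gag 1–900, Pol 901–1908, Env 1909–2828 with G<sub>N</sub> 1909–2329 and
G<sub>C</sub> 2330–2828), the YVDN polymerase tetrad at a fixed Pol offset,
23-residue TM stretches (drawn from {L,I,V,F,A}, longer than the TM
caller's 19-residue window) at the cassette C-termini, one sequon at
G<sub>C</sub> 414, 30 cysteines in G<sub>C</sub> 1–443, and untranslated
linkers sized so the element spans exactly 9,204 nt. Other polyprotein
lengths scale these anchors proportionally. Background is i.i.d. sequence
at GC fraction 0.42 (hookworm-like).

The default benchmark (seed 1) plants 10 intact elements at LTR
divergences {0, 0, 0, 0, 0.02, 0.02, 0.02, 0.05, 0.05, 0.05} and 10
decoys: 2 internal-stop, 2 frameshift (one inserted base at 45% of the
ORF), 2 solo-LTR, 2 LTR-truncation (clipped to 80 nt, placed at a contig
end, emulating assembly-edge loss), 2 LTR-degeneration (divergence 0.15).
All elements share one polyprotein with independent synonymous
back-translation (sibling elements); the envelope queries are the planted
cassettes' own translations, emulating a cognate-query screen. Expected
verdicts are derived from *realized* repeat identities and the stated
thresholds, so elements whose sampled divergence happens to cross the 95%
line are labeled accordingly rather than by nominal divergence.

Determinism of planted truth required three construction rules, documented
here because they are what makes exact recovery assertable:

- **Conserved repeat termini.** Planted LTRs begin TG and end CA (the
  canonical retroelement boundary dinucleotides) and the divergence model
  never mutates the terminal two bases. Local alignment therefore never
  trims a diverged repeat's ends, and detected identity coincides with the
  positionwise identity of the emitted pair.
- **Boundary anchor blocks.** The element interior starts and ends with a
  fixed 8-mer over {A,C}, and planting writes the complementary 8-mer over
  {G,T} into the adjacent background, so no alignment can extend across an
  insertion boundary at any small offset.
- **Unique pattern instances.** Accidental Y-X-D-[D/N] tetrads are
  scrubbed from the random backbone (third-position D → E), the
  G<sub>C</sub> region is cleared of stray cysteines and asparagines before
  the census features are planted, and an in-frame stop guards the linker
  immediately upstream of the planted ATG so the longest ORF starts exactly
  at the planted start codon.

What passing the benchmark shows: the screen recovers planted anatomy
exactly and assigns all 20 verdicts correctly, across seeds. What it does
not show: robustness to real-genome complications the generator omits —
host genes, repeat landscapes, nested insertions, indel divergence in
repeats (the mutation model is substitution-only, matching the percent
identities the screen reports), sequencing gaps, and diverged rather than
cognate envelope queries. The accession-based checks exist precisely to
cover the cognate-vs-diverged gap and run when the public sequences are
supplied under `data/accessions/`.

## Problem sizes

The default benchmark genome is ~292 kb over three contigs — large enough
that every decoy class, locus merging, and contig-end truncation are
exercised, while a full screen (two queries, six frames, exact DP) runs in
well under a minute. The empirical-null test for the seeding thresholds
uses 10<sup>5</sup>-nt element-free backgrounds over three seeds; at 50
bits the expected chance-hit count at this scale is ≪ 1, so zero hits is
the expected outcome, not a tuned one.
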