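# evescout

Screening pipeline for **endogenous viral elements (EVEs)** whose envelope
looks phlebovirus-like rather than retrovirus-like.

Nematode genomes carry belpaovirus-class LTR retroelements in which the Env
position of the Gag-Pol-Env polyprotein is occupied not by a class I
(α-helical, single-pass) retroviral glycoprotein but by a tandem of two
phenuivirus-like glycoprotein cassettes, G<sub>N</sub> and G<sub>C</sub> —
the receptor-binding and class II fusion proteins of phleboviruses. Finding
an *intact* element of this kind in an assembly requires a chain of
evidence, and `evescout` implements that chain end to end:

1. **Homology seeding** — exact six-frame Smith–Waterman (affine gaps,
   BLOSUM62, gap 11/1) of envelope-protein queries against the assembly,
   with an optional second-iteration position-specific scoring matrix
   (PSSM) scan. Scores are reported in bits via the Karlin–Altschul map
   `S' = (λS − ln K)/ln 2`; E-values are database-size-dependent and are
   deliberately not computed.
2. **Terminal repeats** — local alignment of the locus flanks detects the
   long terminal repeat (LTR) pair, reports percent identity over aligned
   columns, and classifies it {intact, degenerate, truncated, solo, none}.
   Identical LTRs mean recent integration, because both copies derive from
   one template at insertion.
3. **Polyprotein integrity** — the longest ATG→stop reading frame over six
   frames must be stop-free, start at ATG, reach a minimum codon count, and
   cover most of the inter-LTR interior ("no introns"). The
   reverse-transcriptase polymerase-site tetrad Y-X-D-[D/N] is located and
   classified (canonical YxDD vs the YVDN variant typical of nematode
   belpaoviruses).
4. **Envelope architecture** — Kyte–Doolittle hydropathy (window 19,
   threshold 1.6) predicts transmembrane helices; the Env is
   phlebovirus-like iff a G<sub>C</sub>-query hit occupies the C-terminal
   portion, a distinct upstream G<sub>N</sub>-like region exists, and the
   G<sub>C</sub> region carries exactly one C-terminal TM. N-glycosylation
   sequons (N-X-[S/T], X ≠ P) and cysteines are censused.
5. **Phylogeny** — progressive alignment (k-mer NJ guide tree,
   profile–profile merging) feeds Poisson-corrected distances
   `d = −ln(1 − p)` into classic neighbor joining, for nearest-neighbor
   placement of candidate RT sequences.

A verdict combines the stages: `intact_EVE_phlebovirus_env` requires an
intact LTR pair **and** a complete polyprotein **and** the tandem
G<sub>N</sub>/G<sub>C</sub> architecture; elements with a complete
polyprotein but degenerate/truncated repeats fall into
`complete_polyprotein_other_env`, interrupted ones into `incomplete`.

The package also ships a first-class **synthetic genome generator**
(`evescout.synth`) that plants elements with exactly this anatomy — plus
decoys with internal stops, frameshifts, solo LTRs, truncated and
degenerate LTRs — and emits ground truth, so the whole screen is testable
without downloading anything.

## Worked example

```bash
$ evescout simulate --seed 1 --out-prefix bench
wrote bench.genome.fasta (291834 nt, 20 planted loci), bench.queries.fasta, bench.truth.gff3

$ evescout screen bench.genome.fasta bench.queries.fasta -o screen_out
18 candidate loci -> screen_out/report.tsv

$ head -3 screen_out/report.tsv
locus_id	element_length_bp	ltr_length_bp	ltr_identity_pct	polyprotein_length_aa	rt_motif	env_class	verdict
chr_sim:4095-16854	9204	271	100.0	2828	YVDN	phlebovirus_like_GN_GC	intact_EVE_phlebovirus_env
chr_sim:19299-32058	9204	271	100.0	2828	YVDN	phlebovirus_like_GN_GC	intact_EVE_phlebovirus_env
```

Each report row is one screened locus: a 9,204-bp element bracketed by
271-nt LTRs at 100% identity encodes a single 2,828-residue Gag-Pol-Env
polyprotein carrying the YVDN polymerase-site variant and a tandem
G<sub>N</sub>/G<sub>C</sub> envelope — the full evidence chain for a
recently integrated, intact EVE. The 20 planted loci yield 18 candidate
rows because solo-LTR decoys carry no envelope homology and are never
seeded (they count as `rejected`).

Other subcommands (`search`, `ltr`, `orf`, `env`, `phylo`, `validate`)
expose the individual stages on single inputs; `evescout screen
--print-config` dumps every threshold with its default.

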