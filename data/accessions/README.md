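# Public accession sequences (user-supplied)

The accession-based checks in `tests/test_acceptance.py` and the optional
real-locus computations in `scripts/acceptance.py` read plain FASTA files
from this directory. They are **not** bundled: fetch them once from NCBI /
UniProt (e.g. with EDirect `efetch` or the web interface) and save them
under the names below. Without these files the accession-based tests fail
with a message pointing here; the synthetic-benchmark tests do not need
them.

| file | contents |
| --- | --- |
| `atlas_locus.fasta` | the EVE locus region of GenBank **JARK01001356.1** covering gene *Acey_s0020.g108* (the 9,204-nt element plus ≥ 1.5 kb of flank on each side) |
| `gc_queries.fasta` | envelope fusion-protein queries: Rift Valley fever virus G_C (UniProt **P03518**, G_C portion) and optionally DABV **AGM33042.1** / HRTV **AFP33394.1**; a G_N query may be added with `GN` in its FASTA id |
| `rt_panel.fasta` | reverse-transcriptase domain sequences: the Atlas polyprotein RT (from UniProt **A0A016UZK2**; id containing `Atlas`), Cer13 (GenBank **Z81510.2**, gene Y75D11A.5; id containing `Cer13`), and the belpaovirus RT panel (GenBank **EYC27361.1**, **EYC19962.1**, **EYC07469.1**, **EYB80846.1**, plus **AF060859.1**, **Z29712.1**, **L09635.1**, **U23420.1**, **AY180917.1**, **D83207.1**, **AF537216.1** translations) |
| `acey_assembly.fasta` | the *Ancylostoma ceylanicum* genome assembly (JARK01 WGS set) — only needed for the genome-wide screen check (~1–2 h) |

All files are ordinary uncompressed FASTA.
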