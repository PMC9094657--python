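"""Polyprotein integrity: longest ORF, completeness verdicts, and the
reverse-transcriptase polymerase-site motif.

An element is considered to encode a complete Gag-Pol-Env polyprotein when
a single ATG-initiated reading frame, free of internal stops, reaches a
minimum codon count and covers most of the inter-LTR interior ("no
introns" is operationalized as this uninterrupted coverage — no splice-site
modeling). The polymerase-site tetrad Y-X-D-[D/N] distinguishes the
canonical retroelement YxDD from the YVDN variant characteristic of
nematode belpaoviruses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import revcomp, translate

DEFAULT_MIN_CODONS = 1500
DEFAULT_MIN_COVERAGE = 0.8
MIN_REPORTABLE_CODONS = 100
#: residues looked back from the polymerase motif to anchor the Pol start
DEFAULT_POL_BACK = 150

_MOTIF_RE = re.compile(r"Y.D[DN]")


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame, coordinates 1-based inclusive on the input
    sequence's forward strand."""

    start: int
    end: int  # includes the terminal stop codon when present
    strand: str
    frame: int  # 0..2 offset on the reading strand
    translated_length: int
    internal_stop_count: int
    has_start_codon: bool
    has_terminal_stop: bool
    protein: str


@dataclass(frozen=True)
class MotifHit:
    """Polymerase-site tetrad match."""

    motif: str
    position: int  # 1-based residue of the Y; 0 when absent
    variant: str  # canonical_YXDD | variant_YXDN | none


def _orfs_in_translation(prot: str):
    """Yield (met_index, stop_index_or_None) for the longest ORF of every
    inter-stop segment (first Met to segment stop)."""
    seg_start = 0
    for i, aa in enumerate(prot + "*"):
        if aa == "*":
            m = prot.find("M", seg_start, i)
            if m != -1:
                yield m, i if i < len(prot) else None
            seg_start = i + 1


def longest_orf(seq: str, min_codons: int = MIN_REPORTABLE_CODONS) -> OrfRecord | None:
    """Longest ATG-to-stop reading frame over both strands and all frames.

    Ties break toward the forward strand, then the leftmost start. Returns
    None when no ORF reaches min_codons (the "no ORF" verdict).
    """
    n = len(seq)
    candidates = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in (0, 1, 2):
            prot = translate(s, frame)
            for m, stop in _orfs_in_translation(prot):
                length = (stop if stop is not None else len(prot)) - m
                if length < min_codons:
                    continue
                nt_start = frame + 3 * m + 1
                nt_end = frame + 3 * (stop + 1) if stop is not None else frame + 3 * len(prot)
                if strand == "-":
                    nt_start, nt_end = n - nt_end + 1, n - nt_start + 1
                candidates.append(
                    OrfRecord(
                        start=nt_start, end=nt_end, strand=strand, frame=frame,
                        translated_length=length,
                        internal_stop_count=0,  # ATG-to-stop by construction
                        has_start_codon=True,
                        has_terminal_stop=stop is not None,
                        protein=prot[m : m + length],
                    )
                )
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda o: (-o.translated_length, 0 if o.strand == "+" else 1, o.start),
    )


def check_integrity(
    orf: OrfRecord | None,
    interior_length: int,
    min_codons: int = DEFAULT_MIN_CODONS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> str:
    """Verdict {complete, interrupted, absent} for the inter-LTR interior."""
    if interior_length <= 0 or orf is None:
        return "absent"
    covered = (orf.end - orf.start + 1) / interior_length
    if (
        orf.internal_stop_count == 0
        and orf.has_start_codon
        and orf.translated_length >= min_codons
        and covered >= min_coverage
    ):
        return "complete"
    return "interrupted"


def scan_polymerase_motif(
    polyprotein: str,
    search_span: tuple[int, int] | None = None,
    full_length: bool = False,
) -> MotifHit:
    """First Y-X-D-[D/N] in the search span (default: the middle third,
    where Pol lies). Positions are 1-based in the polyprotein."""
    L = len(polyprotein)
    if full_length:
        lo, hi = 1, L
    elif search_span is not None:
        lo, hi = search_span
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"search span {search_span} outside polyprotein")
    else:
        lo, hi = L // 3 + 1, (2 * L) // 3
    m = _MOTIF_RE.search(polyprotein, lo - 1, hi)
    if m is None:
        return MotifHit(motif="", position=0, variant="none")
    motif = m.group()
    variant = "canonical_YXDD" if motif[3] == "D" else "variant_YXDN"
    return MotifHit(motif=motif, position=m.start() + 1, variant=variant)


def partition_polyprotein(
    polyprotein_length: int,
    motif: MotifHit | None,
    env_spans: list[tuple[int, int]],
    pol_back: int = DEFAULT_POL_BACK,
) -> dict[str, tuple[int, int] | None]:
    """Gag/Pol/Env partition from the motif anchor and envelope hit spans.

    Env is the union of envelope-query hit spans; Pol runs from pol_back
    residues before the polymerase motif to the Env start; Gag is the
    N-terminal remainder. Missing anchors leave spans undetermined (None).
    """
    L = polyprotein_length
    env = None
    if env_spans:
        env = (min(s for s, _ in env_spans), max(e for _, e in env_spans))
        env = (max(1, env[0]), min(L, env[1]))
    pol = None
    gag = None
    if motif is not None and motif.variant != "none":
        pol_start = max(1, motif.position - pol_back)
        pol_end = env[0] - 1 if env else min(L, motif.position + pol_back)
        if pol_end >= pol_start:
            pol = (pol_start, pol_end)
            if pol_start > 1:
                gag = (1, pol_start - 1)
    return {"gag": gag, "pol": pol, "env": env}
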