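"""Envelope architecture: is an Env retrovirus-like or phlebovirus-like?

Retroviral envelopes are single-pass class I fusion proteins: one
C-terminal transmembrane (TM) anchor behind an alpha-helical,
heptad-repeat-bearing ectodomain. The phenuivirus-like architecture is a
tandem of two glycoprotein cassettes, G_N then G_C, each with its own
C-terminal TM, the pair cleaved from one precursor. The classifier works
from sequence only: Kyte-Doolittle hydropathy for TM helices, envelope
query hits for the cassette spans, the N-X-[S/T] sequon rule for
glycosylation sites, and a cysteine census. Cleavage sites are
approximated by cassette boundaries adjacent to TM segments; no
protease-specificity model is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

DEFAULT_WINDOW = 19
DEFAULT_TM_THRESHOLD = 1.6
DEFAULT_TM_MIN_LEN = 17
TM_MERGE_GAP = 5
#: a TM is "C-terminal" to a region when it lies within this many residues
#: of the region's end
CTERM_WINDOW = 60
#: how far upstream of the G_C start a G_N TM may sit and still mark the
#: cassette boundary
GN_TM_SLACK = 40

_HYDROPHOBIC = set("AILMFVWC")


@dataclass(frozen=True)
class TmSegment:
    """A predicted transmembrane helix (1-based residue span)."""

    start: int
    end: int
    mean_hydropathy: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SequonHit:
    """An N-linked glycosylation sequon (N-X-[S/T], X != P)."""

    position: int  # 1-based position of the asparagine
    triplet: str


@dataclass
class EnvArchitecture:
    """Classification result for one envelope protein."""

    env_class: str  # phlebovirus_like_GN_GC | retrovirus_like | unclassified
    gn_span: tuple[int, int] | None = None
    gc_span: tuple[int, int] | None = None
    tm_segments: list[TmSegment] = field(default_factory=list)
    sequons: list[SequonHit] = field(default_factory=list)
    cysteine_count: int = 0


def hydropathy_profile(protein: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered sliding-mean Kyte-Doolittle hydropathy, one value per residue.

    Termini use truncated windows (the mean over however much of the window
    fits). Unknown residues contribute 0.
    """
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    vals = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    n = len(vals)
    if n == 0:
        return vals
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_tm_segments(
    profile: np.ndarray,
    threshold: float = DEFAULT_TM_THRESHOLD,
    min_len: int = DEFAULT_TM_MIN_LEN,
) -> list[TmSegment]:
    """Maximal runs of hydropathy >= threshold, at least min_len residues
    long; runs separated by fewer than TM_MERGE_GAP residues are merged."""
    above = profile >= threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < TM_MERGE_GAP:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [
        TmSegment(
            start=s + 1, end=e + 1,
            mean_hydropathy=float(profile[s : e + 1].mean()),
        )
        for s, e in merged
        if e - s + 1 >= min_len
    ]


def scan_sequons(protein: str) -> list[SequonHit]:
    """All N-X-[S/T] triplets with X != P, 1-based asparagine positions."""
    hits = []
    for i in range(len(protein) - 2):
        if (
            protein[i] == "N"
            and protein[i + 1] != "P"
            and protein[i + 2] in "ST"
        ):
            hits.append(SequonHit(position=i + 1, triplet=protein[i : i + 3]))
    return hits


def count_cysteines(protein: str, span: tuple[int, int] | None = None) -> int:
    """Number of cysteines in a 1-based inclusive span (whole protein when
    span is None; an inverted span counts as empty)."""
    if span is None:
        return protein.count("C")
    s, e = span
    if e < s:
        return 0
    if not (1 <= s and e <= len(protein)):
        raise ValueError(f"span {span} outside protein of length {len(protein)}")
    return protein.count("C", s - 1, e)


def has_heptad_repeat(protein: str, span: tuple[int, int], min_heptads: int = 4) -> bool:
    """Crude coiled-coil detector: a window of min_heptads heptads in which
    at least 6 of the 8 a/d positions (any register) are hydrophobic."""
    s, e = max(1, span[0]), min(len(protein), span[1])
    region = protein[s - 1 : e]
    w = 7 * min_heptads
    for start in range(0, len(region) - w + 1):
        window = region[start : start + w]
        for phase in range(7):
            ad = [
                window[i]
                for i in range(w)
                if (i - phase) % 7 in (0, 3)
            ]
            if sum(1 for aa in ad if aa in _HYDROPHOBIC) >= 6:
                return True
    return False


def classify_env(
    protein: str,
    gc_hits: list[tuple[int, int]] | None = None,
    gn_hits: list[tuple[int, int]] | None = None,
    tm_segments: list[TmSegment] | None = None,
    window: int = DEFAULT_WINDOW,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
    tm_min_len: int = DEFAULT_TM_MIN_LEN,
) -> EnvArchitecture:
    """Decide between tandem G_N/G_C and retrovirus-like architectures.

    gc_hits/gn_hits are residue spans (in `protein` coordinates) of
    alignments to G_C-like and G_N-like envelope queries. The call is
    phlebovirus-like iff a G_C hit occupies the C-terminal portion, a
    distinct upstream G_N-like region exists (own TM or G_N hit), and the
    G_C region carries exactly one C-terminal TM. Deterministic and
    independent of hit-list order.
    """
    if not protein:
        return EnvArchitecture(env_class="unclassified")
    gc_hits = sorted(gc_hits or [])
    gn_hits = sorted(gn_hits or [])
    if tm_segments is None:
        tm_segments = predict_tm_segments(
            hydropathy_profile(protein, window), tm_threshold, tm_min_len
        )
    L = len(protein)

    gc_span = None
    gn_span = None
    env_class = "unclassified"
    if gc_hits:
        gc_lo = min(s for s, _ in gc_hits)
        gc_hi = max(e for _, e in gc_hits)
        cterm = gc_hi >= 0.8 * L
        # G_N evidence: a TM ending just upstream of the G_C hit, or a hit
        # against a G_N query upstream of the G_C region
        gn_tm = [
            t for t in tm_segments
            if t.end < gc_lo + GN_TM_SLACK and t.end >= gc_lo - GN_TM_SLACK
        ]
        gn_query = [h for h in gn_hits if h[0] < gc_lo]
        if cterm and (gn_tm or gn_query):
            # cassette boundary at the end of the G_N TM when one exists
            boundary = max(t.end for t in gn_tm) if gn_tm else gc_lo - 1
            gc_span = (boundary + 1, L)
            gn_start = min(h[0] for h in gn_query) if gn_query else max(
                1, boundary - 420
            )
            gn_span = (gn_start, boundary)
            gc_tms = [
                t for t in tm_segments if t.start >= gc_span[0] and t.end <= gc_span[1]
            ]
            if len(gc_tms) == 1 and gc_tms[0].end >= L - CTERM_WINDOW:
                env_class = "phlebovirus_like_GN_GC"
            else:
                gc_span = gn_span = None
    if env_class == "unclassified" and not gc_hits:
        cterm_tms = [t for t in tm_segments if t.end >= L - CTERM_WINDOW]
        if (
            len(tm_segments) == 1
            and cterm_tms
            and has_heptad_repeat(protein, (max(1, cterm_tms[0].start - 200),
                                            cterm_tms[0].start - 1))
        ):
            env_class = "retrovirus_like"

    sequon_region = gc_span or (1, L)
    sequons = [
        h for h in scan_sequons(protein)
        if sequon_region[0] <= h.position <= sequon_region[1]
    ]
    return EnvArchitecture(
        env_class=env_class,
        gn_span=gn_span,
        gc_span=gc_span,
        tm_segments=tm_segments,
        sequons=sequons,
        cysteine_count=count_cysteines(protein, gc_span),
    )
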