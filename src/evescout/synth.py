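"""Synthetic genomes with planted LTR retroelements and decoys.

The generator emulates the anatomy of an intact belpaovirus-class
endogenous viral element (EVE) with a phlebovirus-like envelope: terminal
direct repeats of configurable length and divergence flanking a single long
Gag-Pol-Env open reading frame, a reverse-transcriptase polymerase-site
tetrad (Y-X-D-[D/N]) in the Pol third, and hydrophobic transmembrane
stretches at the C-termini of the G_N- and G_C-like envelope cassettes.
Decoy classes (internal stop, frameshift, solo LTR, truncated LTR,
degenerate LTR) exercise every rejection rule of the screen.

Default dimensions mirror the best-characterized intact element of this
family: 271-nt LTRs, a 2828-residue polyprotein, and untranslated linkers
sized so the whole element spans 9204 nt. The polyprotein layout uses
Gag 1-900, Pol 901-1908, Env 1909-2828 with G_N 1909-2329 and G_C
2330-2828, a single N-glycosylation sequon at G_C position 414, and 30
cysteines in G_C 1-443; other polyprotein lengths scale these anchors
proportionally.

Construction is made deterministic in the sense that every planted feature
is the *unique* instance of its pattern: accidental polymerase tetrads,
G_C-region cysteines and sequon-forming asparagines in the random backbone
are scrubbed before planting, LTR termini carry the canonical TG...CA
dinucleotides which the divergence model never mutates, and the background
bases flanking each insertion are forced to mismatch the element's terminal
context so planted repeat coordinates are unambiguous under local
alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .scoring import BLOSUM62_BACKGROUND
from .seqio import FeatureRecord, GenomeRecord, ProteinRecord, translate

DISRUPTIONS = (
    "none",
    "internal_stop",
    "frameshift",
    "ltr_truncation",
    "ltr_degeneration",
    "solo_ltr",
)

#: polyprotein layout anchors (1-based residue coordinates at length 2828)
_ANCHOR_LEN = 2828
_ANCHOR_GAG_END = 900
_ANCHOR_POL_END = 1908
_ANCHOR_GN_END = 2329
_MOTIF_OFFSET_IN_POL = 150  # residues from Pol start to the Y-X-D-[D/N] tetrad
_TM_LEN = 23
_SEQUON_GC_POS = 414  # G_C-local residue index of the planted sequon
_GC_CYS_COUNT = 30
_GC_CYS_SPAN = 443  # cysteines planted within G_C 1..443

DEFAULT_LTR_LENGTH = 271
DEFAULT_ORF_LENGTH = 2828  # polyprotein residues, incl. initial Met
DEFAULT_LINKER5 = 100
DEFAULT_LINKER3 = 75
DEFAULT_GC_CONTENT = 0.42
TRUNCATED_LTR_LEN = 80  # < half LTR and < the finder's min repeat length

#: boundary anchor blocks: the element interior starts/ends with BLOCK_IN and
#: plant() writes BLOCK_OUT into the adjacent background, so the two sides of
#: every insertion share no matches at any small alignment offset and the
#: planted repeat coordinates are unambiguous under local alignment
BOUNDARY_BLOCK_IN = "ACACACAC"
BOUNDARY_BLOCK_OUT = "GTGTGTGT"

_NT = np.array(list("ACGT"))
_AA20 = list("ARNDCQEGHILKMFPSTWYV")
_AA_P = np.array([BLOSUM62_BACKGROUND[a] for a in _AA20])
_AA_P = _AA_P / _AA_P.sum()

_CODONS_FOR = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)

_MOTIF_RE = re.compile(r"Y.D[DN]")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class EveSpec:
    """Parameters of one planted element."""

    ltr_length: int = DEFAULT_LTR_LENGTH
    ltr_divergence: float = 0.0
    orf_length: int = DEFAULT_ORF_LENGTH  # residues, incl. Met; 0 only for solo_ltr
    rt_motif: str = "YVDN"
    env_tm_count: int = 2
    disruption: str = "none"
    insertion_site: int | None = None  # 1-based background coordinate

    def __post_init__(self) -> None:
        if self.disruption not in DISRUPTIONS:
            raise ValueError(f"unknown disruption {self.disruption!r}")
        if self.ltr_length < 50:
            raise ValueError("ltr_length must be >= 50")
        if not (0.0 <= self.ltr_divergence < 1.0):
            raise ValueError("ltr_divergence must be in [0, 1)")
        if self.disruption == "solo_ltr":
            if self.orf_length > 0:
                raise ValueError("solo_ltr element cannot carry an ORF")
        elif self.orf_length < 100:
            raise ValueError("orf_length must be >= 100 codons")
        if self.rt_motif and not re.fullmatch(r"Y.D[DN]", self.rt_motif):
            raise ValueError(f"rt_motif {self.rt_motif!r} must match Y-X-D-[D/N]")
        if self.env_tm_count not in (1, 2):
            raise ValueError("env_tm_count must be 1 or 2")


@dataclass
class PlantedTruth:
    """Ground truth for one planted element, in 1-based contig coordinates
    after planting (element-relative before planting)."""

    locus_id: str
    contig: str
    disruption: str
    element_start: int
    element_end: int
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    ltr_length: int
    ltr_identity: float  # percent, realized from the emitted pair
    orf: tuple[int, int] | None  # nt span incl. stop codon
    polyprotein_length: int  # planted residues (pre-disruption)
    motif: str
    motif_pos: int  # 1-based residue in the polyprotein; 0 if absent
    tm_segments: list[tuple[int, int]] = field(default_factory=list)  # residue spans
    gag: tuple[int, int] | None = None
    pol: tuple[int, int] | None = None
    env: tuple[int, int] | None = None
    gn: tuple[int, int] | None = None
    gc: tuple[int, int] | None = None
    sequon_pos: int = 0  # polyprotein residue of the planted sequon N
    expected_ltr_class: str = ""
    expected_verdict: str = ""

    @property
    def element_length(self) -> int:
        return self.element_end - self.element_start + 1

    def shifted(self, offset: int, contig: str) -> "PlantedTruth":
        def mv(span):
            return None if span is None else (span[0] + offset, span[1] + offset)

        return replace(
            self,
            contig=contig,
            element_start=self.element_start + offset,
            element_end=self.element_end + offset,
            ltr5=mv(self.ltr5),
            ltr3=mv(self.ltr3),
            orf=mv(self.orf),
        )


def generate_background(
    length: int, gc: float = DEFAULT_GC_CONTENT, seed=None, contig_id: str = "bg"
) -> GenomeRecord:
    """I.i.d. background sequence with P(G)+P(C) = gc, reproducible under seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be within [0, 1]")
    rng = _as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_NT, size=length, p=p))
    return GenomeRecord(id=contig_id, seq=seq)


def mutate(seq: str, divergence: float, seed=None) -> tuple[str, float]:
    """Per-site substitution with probability = divergence, uniform over the
    three alternative bases. Returns (mutant, realized identity percent)."""
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")
    rng = _as_rng(seed)
    chars = np.array(list(seq))
    hit = rng.random(len(seq)) < divergence
    out = chars.copy()
    for i in np.flatnonzero(hit):
        alts = [b for b in "ACGT" if b != chars[i]]
        out[i] = alts[rng.integers(3)]
    mutant = "".join(out)
    matches = sum(1 for a, b in zip(seq, mutant) if a == b)
    return mutant, 100.0 * matches / len(seq) if seq else 100.0


def polyprotein_layout(length: int) -> dict:
    """Scale the Atlas-like layout anchors to an arbitrary polyprotein length."""

    def sc(x):
        return max(1, round(x * length / _ANCHOR_LEN))

    gag_end = sc(_ANCHOR_GAG_END)
    pol_end = sc(_ANCHOR_POL_END)
    gn_end = sc(_ANCHOR_GN_END)
    layout = {
        "gag": (1, gag_end),
        "pol": (gag_end + 1, pol_end),
        "env": (pol_end + 1, length),
        "gn": (pol_end + 1, gn_end),
        "gc": (gn_end + 1, length),
        # a fixed offset into Pol, kept clear of the Pol/Env boundary so the
        # tetrad stays inside the middle third for any polyprotein length
        "motif_pos": min(gag_end + 1 + _MOTIF_OFFSET_IN_POL, pol_end - 3),
    }
    return layout


def random_polyprotein(
    length: int = DEFAULT_ORF_LENGTH,
    rt_motif: str = "YVDN",
    env_tm_count: int = 2,
    seed=None,
) -> tuple[str, dict]:
    """Draw a random polyprotein and plant the screen's diagnostic features.

    Returns (sequence, layout). The planted polymerase tetrad, sequon,
    G_C cysteines and TM stretches are the unique instances of their
    patterns (accidental instances in the random backbone are scrubbed).
    """
    if length < 100:
        raise ValueError("polyprotein must be >= 100 residues")
    rng = _as_rng(seed)
    layout = polyprotein_layout(length)
    aa = list(rng.choice(_AA20, size=length, p=_AA_P))
    aa[0] = "M"

    gn_s, gn_e = layout["gn"]
    gc_s, gc_e = layout["gc"]
    gc_len = gc_e - gc_s + 1

    # scrub the G_C region: no stray cysteines or asparagines
    for i in range(gc_s - 1, gc_e):
        if aa[i] == "C":
            aa[i] = "S"
        elif aa[i] == "N":
            aa[i] = "Q"

    # planted transmembrane stretches: C-terminus of G_C, optionally of G_N
    tm = []
    hydro = list("LIVFA")
    gc_tm_end = length - 2
    gc_tm_start = gc_tm_end - _TM_LEN + 1
    for i in range(gc_tm_start - 1, gc_tm_end):
        aa[i] = hydro[rng.integers(5)]
    tm.append((gc_tm_start, gc_tm_end))
    if env_tm_count == 2:
        gn_tm_end = gn_e
        gn_tm_start = gn_tm_end - _TM_LEN + 1
        for i in range(gn_tm_start - 1, gn_tm_end):
            aa[i] = hydro[rng.integers(5)]
        tm.insert(0, (gn_tm_start, gn_tm_end))
    layout["tm"] = tm

    # planted sequon (N-G-T) at the G_C-local anchor position, scaled
    sequon_local = min(round(_SEQUON_GC_POS * gc_len / 499), gc_len - 2)
    sequon_pos = gc_s + sequon_local - 1
    if not (gc_tm_start - 1 <= sequon_pos <= gc_tm_end):
        aa[sequon_pos - 1] = "N"
        aa[sequon_pos] = "G"
        aa[sequon_pos + 1] = "T"
    layout["sequon_pos"] = sequon_pos

    # planted G_C cysteines, evenly spread over the ectodomain span
    cys_span = min(round(_GC_CYS_SPAN * gc_len / 499), gc_len)
    cys_pos = np.linspace(5, cys_span - 3, _GC_CYS_COUNT).round().astype(int)
    cys_final = []
    for p in cys_pos:
        poly = gc_s + int(p) - 1
        if abs(poly - sequon_pos) <= 2 or gc_tm_start <= poly <= gc_tm_end:
            continue
        aa[poly - 1] = "C"
        cys_final.append(int(p))
    layout["gc_cysteines"] = cys_final

    # plant the polymerase-site tetrad, then scrub accidental instances
    mpos = layout["motif_pos"]
    for k, r in enumerate(rt_motif):
        aa[mpos - 1 + k] = r
    seq = "".join(aa)
    while True:
        stray = [
            m.start()
            for m in _MOTIF_RE.finditer(seq)
            if m.start() != mpos - 1
        ]
        if not stray:
            break
        chars = list(seq)
        for s in stray:
            chars[s + 2] = "E"  # break the D at position 3 of the tetrad
        seq = "".join(chars)
    layout["motif"] = rt_motif
    return seq, layout


def back_translate(protein: str, seed=None) -> str:
    """Random synonymous back-translation (standard code), plus a TAA stop."""
    rng = _as_rng(seed)
    codons = []
    for aa in protein:
        options = _CODONS_FOR.get(aa)
        if options is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons) + "TAA"


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(_NT, size=n)) if n > 0 else ""


def _make_ltr(rng, length: int) -> str:
    # canonical TG...CA termini; never touched by the divergence model
    return "TG" + _random_nt(rng, length - 4) + "CA"


def _full_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * matches / n if n else 100.0


def assemble_eve(
    spec: EveSpec,
    seed=None,
    polyprotein: str | None = None,
    layout: dict | None = None,
    linker5: int = DEFAULT_LINKER5,
    linker3: int = DEFAULT_LINKER3,
    locus_id: str = "element",
) -> tuple[str, PlantedTruth]:
    """Build one element sequence plus its ground truth (element-relative,
    1-based coordinates).

    Structure: LTR5 + linker5 + ORF(ATG..stop) + linker3 + LTR3, where LTR3
    is a mutated copy of LTR5 at the spec's divergence. The last in-frame
    codon of linker5 is a stop, so the planted ATG starts the longest ORF.
    A shared polyprotein/layout may be passed in (sibling elements); the
    back-translation is always drawn fresh, giving synonymous divergence
    between siblings.
    """
    rng = _as_rng(seed)
    ltr5 = _make_ltr(rng, spec.ltr_length)

    if spec.disruption == "solo_ltr":
        truth = PlantedTruth(
            locus_id=locus_id, contig="", disruption="solo_ltr",
            element_start=1, element_end=spec.ltr_length,
            ltr5=(1, spec.ltr_length), ltr3=None,
            ltr_length=spec.ltr_length, ltr_identity=100.0,
            orf=None, polyprotein_length=0, motif="", motif_pos=0,
        )
        return ltr5, truth

    if polyprotein is None:
        polyprotein, layout = random_polyprotein(
            spec.orf_length, spec.rt_motif, spec.env_tm_count, seed=rng
        )
    assert layout is not None
    if len(polyprotein) != spec.orf_length:
        raise ValueError("polyprotein length does not match spec.orf_length")

    orf_nt = back_translate(polyprotein, seed=rng)

    if spec.disruption == "internal_stop":
        stop_codon = len(polyprotein) // 2
        orf_nt = orf_nt[: 3 * stop_codon] + "TAA" + orf_nt[3 * stop_codon + 3 :]
    elif spec.disruption == "frameshift":
        at = 3 * int(0.45 * len(polyprotein))
        orf_nt = orf_nt[:at] + "A" + orf_nt[at:]

    link5 = _random_nt(rng, linker5)
    nb = len(BOUNDARY_BLOCK_IN)
    if linker5 >= nb + 3:
        link5 = BOUNDARY_BLOCK_IN + link5[nb:]
    if linker5 >= 3:
        # in-frame guard stop immediately upstream of the planted ATG
        link5 = link5[:-3] + "TAA"
    link3 = _random_nt(rng, linker3)
    if linker3 >= nb:
        link3 = link3[:-nb] + BOUNDARY_BLOCK_IN
    interior = link5 + orf_nt + link3

    if spec.disruption == "ltr_truncation":
        ltr3 = ltr5[:TRUNCATED_LTR_LEN]
        identity = 100.0
    else:
        div = spec.ltr_divergence
        core, _ = mutate(ltr5[2:-2], div, seed=rng)
        ltr3 = ltr5[:2] + core + ltr5[-2:]
        identity = _full_identity(ltr5, ltr3)

    element = ltr5 + interior + ltr3
    L = spec.ltr_length
    orf_start = L + linker5 + 1
    orf_end = L + linker5 + len(orf_nt)
    ltr3_start = L + len(interior) + 1
    truth = PlantedTruth(
        locus_id=locus_id, contig="", disruption=spec.disruption,
        element_start=1, element_end=len(element),
        ltr5=(1, L), ltr3=(ltr3_start, len(element)),
        ltr_length=min(L, len(ltr3)), ltr_identity=identity,
        orf=(orf_start, orf_end),
        polyprotein_length=len(polyprotein),
        motif=layout["motif"], motif_pos=layout["motif_pos"],
        tm_segments=list(layout["tm"]),
        gag=layout["gag"], pol=layout["pol"], env=layout["env"],
        gn=layout["gn"], gc=layout["gc"],
        sequon_pos=layout["sequon_pos"],
    )
    return element, truth


def plant(
    background: GenomeRecord,
    elements: list[tuple[str, PlantedTruth]],
    sites: list[int],
) -> tuple[GenomeRecord, list[PlantedTruth]]:
    """Insert elements into a background contig at 1-based sites.

    Sites refer to background coordinates (the element is inserted *before*
    that base) and must be distinct, ascending, and >= 8 nt apart. Truth
    coordinates come back shifted to the final contig. The four background
    bases on each side of every insertion are adjusted to mismatch the
    element's boundary context (see module docstring).
    """
    if len(elements) != len(sites):
        raise ValueError("one site per element required")
    if sites != sorted(sites) or len(set(sites)) != len(sites):
        raise ValueError("insertion sites must be ascending and distinct")
    for a, b in zip(sites, sites[1:]):
        if b - a < 8:
            raise ValueError("insertion sites overlap (min separation 8 nt)")
    if sites and not (1 <= sites[0] and sites[-1] <= background.length + 1):
        raise ValueError("insertion site outside background")

    bg = list(background.seq)
    pieces = []
    truths = []
    prev = 0
    offset = 0
    for (elem, truth), site in zip(elements, sites):
        _sharpen(bg, site, elem, truth)
        pieces.append("".join(bg[prev : site - 1]))
        pieces.append(elem)
        truths.append(truth.shifted(site - 1 + offset, background.id))
        offset += len(elem)
        prev = site - 1
    pieces.append("".join(bg[prev:]))
    genome = GenomeRecord(id=background.id, seq="".join(pieces))
    return genome, truths


def _sharpen(bg: list, site: int, elem: str, truth: PlantedTruth) -> None:
    """Write the outside boundary block into the background on both sides of
    the insertion (solo repeats excepted), so no alignment can extend across
    the element boundary at any small offset."""
    if truth.ltr3 is None:
        return
    for i, c in enumerate(BOUNDARY_BLOCK_OUT):
        j = site - 1 + i  # first background bases after the element
        if j < len(bg):
            bg[j] = c
        j = site - 2 - i  # background bases before the element, outward
        if j >= 0:
            bg[j] = BOUNDARY_BLOCK_OUT[-(i + 1)]


def truth_features(truths: list[PlantedTruth]) -> list[FeatureRecord]:
    """Ground truth as GFF3-ready features (contig coordinates)."""
    feats = []
    for t in truths:
        attrs = {
            "ID": t.locus_id,
            "disruption": t.disruption,
            "ltr_identity": f"{t.ltr_identity:.2f}",
            "expected_verdict": t.expected_verdict or ".",
        }
        feats.append(
            FeatureRecord(t.contig, t.element_start, t.element_end, "+", "element", attrs)
        )
        for name, span in (("ltr5", t.ltr5), ("ltr3", t.ltr3)):
            if span:
                feats.append(
                    FeatureRecord(
                        t.contig, span[0], span[1], "+", "LTR",
                        {"Parent": t.locus_id, "which": name},
                    )
                )
        if t.orf:
            feats.append(
                FeatureRecord(
                    t.contig, t.orf[0], t.orf[1], "+", "ORF",
                    {"Parent": t.locus_id, "residues": str(t.polyprotein_length)},
                )
            )
    return feats


@dataclass
class Benchmark:
    """The default planted benchmark: contigs, truths, and Env queries."""

    contigs: list[GenomeRecord]
    truths: list[PlantedTruth]
    queries: list[ProteinRecord]
    polyprotein: str
    layout: dict


#: benchmark composition: 10 intact elements across LTR divergences, plus
#: 10 decoys covering every disruption class
BENCHMARK_INTACT_DIVERGENCES = (0.0, 0.0, 0.0, 0.0, 0.02, 0.02, 0.02, 0.05, 0.05, 0.05)
BENCHMARK_DECOYS = (
    "internal_stop", "internal_stop",
    "frameshift", "frameshift",
    "solo_ltr", "solo_ltr",
    "ltr_truncation", "ltr_truncation",
    "ltr_degeneration", "ltr_degeneration",
)
BENCHMARK_DEGENERATE_DIVERGENCE = 0.15
DEFAULT_BENCHMARK_SEED = 1

_SPACING = 6000  # background nt between insertion sites


def make_benchmark(
    seed: int = DEFAULT_BENCHMARK_SEED,
    intact_threshold: float = 95.0,
    min_codons: int = 1500,
) -> Benchmark:
    """Build the default recovery benchmark.

    One main contig carries the 10 intact elements and the non-truncation
    decoys; each LTR-truncation decoy sits at the end of its own contig
    (emulating an element cut by the assembly edge). All elements share one
    polyprotein (sibling EVEs) with independent synonymous back-translation.
    Expected verdicts are derived from realized LTR identities and the
    stated thresholds.
    """
    rng = np.random.default_rng(seed)
    poly_rng, bg_rng, elem_rng, trunc_rng = rng.spawn(4)

    polyprotein, layout = random_polyprotein(seed=poly_rng)
    queries = [
        ProteinRecord("GN_query", polyprotein[layout["gn"][0] - 1 : layout["gn"][1]]),
        ProteinRecord("GC_query", polyprotein[layout["gc"][0] - 1 : layout["gc"][1]]),
    ]

    specs: list[EveSpec] = []
    for d in BENCHMARK_INTACT_DIVERGENCES:
        specs.append(EveSpec(ltr_divergence=d))
    for dis in BENCHMARK_DECOYS:
        if dis == "solo_ltr":
            specs.append(EveSpec(orf_length=0, disruption=dis))
        elif dis == "ltr_degeneration":
            specs.append(
                EveSpec(ltr_divergence=BENCHMARK_DEGENERATE_DIVERGENCE, disruption=dis)
            )
        elif dis == "ltr_truncation":
            specs.append(EveSpec(disruption=dis))
        else:
            specs.append(EveSpec(disruption=dis))

    main_specs = [s for s in specs if s.disruption != "ltr_truncation"]
    trunc_specs = [s for s in specs if s.disruption == "ltr_truncation"]

    sub_rngs = elem_rng.spawn(len(main_specs))
    assembled = []
    for i, (s, r) in enumerate(zip(main_specs, sub_rngs)):
        label = f"planted_{i+1:02d}_{s.disruption}"
        if s.disruption == "solo_ltr":
            assembled.append(assemble_eve(s, seed=r, locus_id=label))
        else:
            assembled.append(
                assemble_eve(s, seed=r, polyprotein=polyprotein, layout=layout,
                             locus_id=label)
            )
    background = generate_background(
        (len(main_specs) + 1) * _SPACING, seed=bg_rng, contig_id="chr_sim"
    )
    sites = [(i + 1) * _SPACING for i in range(len(main_specs))]
    genome, truths = plant(background, assembled, sites)
    contigs = [genome]

    for j, (s, r) in enumerate(zip(trunc_specs, trunc_rng.spawn(len(trunc_specs)))):
        label = f"planted_trunc_{j+1}"
        elem, truth = assemble_eve(
            s, seed=r, polyprotein=polyprotein, layout=layout, locus_id=label
        )
        bg = generate_background(_SPACING, seed=r, contig_id=f"ctg_trunc{j+1}")
        bg_seq = bg.seq[: -len(BOUNDARY_BLOCK_OUT)] + BOUNDARY_BLOCK_OUT
        contig = GenomeRecord(id=bg.id, seq=bg_seq + elem)
        truths.append(truth.shifted(bg.length, contig.id))
        contigs.append(contig)

    for t in truths:
        _label_truth(t, intact_threshold, min_codons)
    return Benchmark(
        contigs=contigs, truths=truths, queries=queries,
        polyprotein=polyprotein, layout=layout,
    )


def _label_truth(t: PlantedTruth, intact_threshold: float, min_codons: int) -> None:
    if t.disruption == "solo_ltr":
        t.expected_ltr_class = "solo"
        t.expected_verdict = "rejected"
    elif t.disruption == "ltr_truncation":
        t.expected_ltr_class = "truncated"
        t.expected_verdict = "complete_polyprotein_other_env"
    elif t.disruption in ("internal_stop", "frameshift"):
        t.expected_ltr_class = (
            "intact" if t.ltr_identity >= intact_threshold else "degenerate"
        )
        t.expected_verdict = "incomplete"
    else:  # none / ltr_degeneration
        if t.ltr_identity >= intact_threshold:
            t.expected_ltr_class = "intact"
            t.expected_verdict = "intact_EVE_phlebovirus_env"
        else:
            t.expected_ltr_class = "degenerate"
            t.expected_verdict = "complete_polyprotein_other_env"
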