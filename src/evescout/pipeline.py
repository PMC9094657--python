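"""Orchestration: homology seeding -> LTR -> ORF -> Env -> verdict.

The screen takes a genome and envelope-protein queries, seeds candidate
loci from translated homology hits, brackets each locus with generous
flanks (the envelope cassette sits near the 3' repeat, so the 5'-ward
flank must bridge the whole Gag-Pol region back to the 5' repeat), and
runs the per-locus evidence chain. The verdict taxonomy separates the
fully intact case (intact repeat pair AND complete polyprotein AND tandem
G_N/G_C envelope) from elements whose polyprotein is complete but whose
repeats or envelope fall short, from interrupted elements, from dismissed
loci.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

from . import envarch, ltr, orf, search
from .config import ScreenConfig
from .scoring import load_blosum62
from .seqio import FeatureRecord, GenomeRecord, ProteinRecord

logger = logging.getLogger(__name__)

VERDICTS = (
    "intact_EVE_phlebovirus_env",
    "complete_polyprotein_other_env",
    "incomplete",
    "rejected",
)


@dataclass
class EveCandidate:
    """One screened locus: the row type of the final report table."""

    locus_id: str
    contig: str
    locus_span: tuple[int, int]
    ltr_pair: ltr.LtrPair | None
    ltr_class: str
    element_span: tuple[int, int] | None  # contig coordinates
    element_length: int
    orf_record: orf.OrfRecord | None  # coordinates within the interior seq
    orf_contig_span: tuple[int, int] | None
    integrity: str
    motif: orf.MotifHit | None
    partition: dict
    env: envarch.EnvArchitecture | None
    verdict: str
    polyprotein: str = ""
    #: union span of fusion-protein (G_C) query hits on the polyprotein —
    #: the numbering anchor for cassette-local residue positions
    gc_hit_span: tuple[int, int] | None = None

    def as_row(self) -> dict:
        pair = self.ltr_pair
        return {
            "locus_id": self.locus_id,
            "element_length_bp": self.element_length or 0,
            "ltr_length_bp": pair.length if pair and pair.found else 0,
            "ltr_identity_pct": round(pair.identity, 2) if pair and pair.found else 0.0,
            "polyprotein_length_aa": (
                self.orf_record.translated_length if self.orf_record else 0
            ),
            "rt_motif": self.motif.motif if self.motif and self.motif.motif else "none",
            "env_class": self.env.env_class if self.env else "unclassified",
            "verdict": self.verdict,
        }

    def as_json(self) -> dict:
        d = {
            "locus_id": self.locus_id,
            "contig": self.contig,
            "locus_span": list(self.locus_span),
            "ltr_class": self.ltr_class,
            "element_span": list(self.element_span) if self.element_span else None,
            "element_length": self.element_length,
            "integrity": self.integrity,
            "verdict": self.verdict,
        }
        if self.ltr_pair and self.ltr_pair.found:
            d["ltr"] = {
                "length": self.ltr_pair.length,
                "identity_pct": round(self.ltr_pair.identity, 3),
            }
        if self.orf_record:
            d["polyprotein_length"] = self.orf_record.translated_length
        if self.motif:
            d["rt_motif"] = asdict(self.motif)
        if self.gc_hit_span:
            d["gc_hit_span"] = list(self.gc_hit_span)
        if self.env:
            d["env"] = {
                "class": self.env.env_class,
                "gn_span": list(self.env.gn_span) if self.env.gn_span else None,
                "gc_span": list(self.env.gc_span) if self.env.gc_span else None,
                "tm_count": len(self.env.tm_segments),
                "sequons": [s.position for s in self.env.sequons],
                "cysteine_count": self.env.cysteine_count,
            }
        return d


def split_queries(queries: list[ProteinRecord]) -> tuple[list, list]:
    """Partition envelope queries into G_N-like and G_C-like panels by id
    convention: ids containing 'GN' are receptor-binding (G_N) queries,
    everything else is treated as a fusion-protein (G_C) query."""
    gn = [q for q in queries if "GN" in q.id.upper()]
    gc = [q for q in queries if q not in gn]
    return gn, gc


def _cluster_loci(hits: list[search.AlignmentHit], merge_gap: int) -> dict[str, list[list]]:
    """Group hits (any query/frame) into loci per contig by interval gap."""
    per_contig: dict[str, list] = {}
    for h in hits:
        per_contig.setdefault(h.target_id, []).append(h)
    loci = {}
    for contig, hs in per_contig.items():
        hs.sort(key=lambda h: h.t_start)
        groups = []
        for h in hs:
            if groups and h.t_start - max(x.t_end for x in groups[-1]) - 1 <= merge_gap:
                groups[-1].append(h)
            else:
                groups.append([h])
        loci[contig] = groups
    return loci


def _hit_residue_span(hit, orf_cstart: int, orf_cend: int, strand: str, plen: int):
    """Map a hit's contig nt span onto polyprotein residue coordinates."""
    s = max(hit.t_start, orf_cstart)
    e = min(hit.t_end, orf_cend)
    if e < s:
        return None
    if strand == "+":
        r1 = (s - orf_cstart) // 3 + 1
        r2 = (e - orf_cstart) // 3 + 1
    else:
        r1 = (orf_cend - e) // 3 + 1
        r2 = (orf_cend - s) // 3 + 1
    return max(1, r1), min(plen, r2)


def _residue_to_nt(r1: int, r2: int, orf_cstart: int, orf_cend: int, strand: str):
    if strand == "+":
        return orf_cstart + 3 * (r1 - 1), orf_cstart + 3 * r2 - 1
    return orf_cend - 3 * r2 + 1, orf_cend - 3 * (r1 - 1)


def analyze_locus(
    contig: GenomeRecord,
    locus_start: int,
    locus_end: int,
    locus_hits: list[search.AlignmentHit],
    gn_ids: set[str],
    config: ScreenConfig,
    locus_id: str,
) -> EveCandidate:
    """Run the per-locus evidence chain on one seeded window."""
    locus_seq = contig.seq[locus_start - 1 : locus_end]
    offset = locus_start - 1

    pair = ltr.find_ltr_pair(
        locus_seq,
        flank_window=config.ltr_flank_window,
        min_len=config.ltr_min_len,
        max_len=config.ltr_max_len,
        match=config.ltr_match,
        mismatch=config.ltr_mismatch,
        gap_open=config.ltr_gap_open,
        gap_extend=config.ltr_gap_extend,
        min_score=config.ltr_min_score,
    )
    ltr_class = ltr.classify(
        pair,
        locus_offset=offset,
        contig_length=contig.length,
        intact_threshold=config.intact_threshold,
        min_len=config.ltr_min_len,
        end_tolerance=config.end_tolerance,
    )
    logger.info(
        "stage=ltr locus=%s class=%s identity=%.2f cols=%d",
        locus_id, ltr_class, pair.identity, pair.aligned_columns,
    )

    if ltr_class in {"intact", "degenerate"}:
        (e_s, e_e), e_len = ltr.delimit_element(pair)
        interior_span = (pair.ltr5[1] + 1, pair.ltr3[0] - 1)
    elif ltr_class == "truncated":
        e_s, e_e = pair.ltr5[0], pair.ltr3[1]
        e_len = e_e - e_s + 1
        interior_span = (pair.ltr5[1] + 1, pair.ltr3[0] - 1)
    else:
        # no repeat bracket: fall back to the hit envelope plus margins
        e_s = e_e = None
        e_len = 0
        interior_span = (1, len(locus_seq))

    int_s, int_e = interior_span
    interior_seq = locus_seq[int_s - 1 : int_e]
    orf_rec = orf.longest_orf(interior_seq) if len(interior_seq) >= 300 else None
    integrity = orf.check_integrity(
        orf_rec, len(interior_seq), config.min_codons, config.min_orf_coverage
    )
    logger.info(
        "stage=orf locus=%s integrity=%s length=%d",
        locus_id, integrity, orf_rec.translated_length if orf_rec else 0,
    )

    motif_hit = None
    partition: dict = {"gag": None, "pol": None, "env": None}
    env_arch = None
    orf_contig_span = None
    gc_hit_span = None
    if orf_rec is not None:
        poly = orf_rec.protein
        motif_hit = orf.scan_polymerase_motif(poly, full_length=config.motif_full_scan)
        orf_cstart = offset + int_s - 1 + orf_rec.start
        orf_cend = offset + int_s - 1 + orf_rec.end
        orf_contig_span = (orf_cstart, orf_cend)
        gn_spans, gc_spans = [], []
        for h in locus_hits:
            span = _hit_residue_span(h, orf_cstart, orf_cend, orf_rec.strand, len(poly))
            if span is None:
                continue
            (gn_spans if h.query_id in gn_ids else gc_spans).append(span)
        if gc_spans:
            gc_hit_span = (
                min(s for s, _ in gc_spans), max(e for _, e in gc_spans)
            )
        partition = orf.partition_polyprotein(
            len(poly), motif_hit, gn_spans + gc_spans, config.pol_motif_back
        )
        env_arch = envarch.classify_env(
            poly, gc_spans, gn_spans,
            window=config.tm_window,
            tm_threshold=config.tm_threshold,
            tm_min_len=config.tm_min_len,
        )
        logger.info(
            "stage=env locus=%s class=%s motif=%s",
            locus_id, env_arch.env_class, motif_hit.motif or "none",
        )

    verdict = _verdict(ltr_class, integrity, env_arch, pair, orf_rec)
    logger.info("stage=verdict locus=%s verdict=%s", locus_id, verdict)

    element_span = (offset + e_s, offset + e_e) if e_s is not None else None
    return EveCandidate(
        locus_id=locus_id,
        contig=contig.id,
        locus_span=(locus_start, locus_end),
        ltr_pair=pair,
        ltr_class=ltr_class,
        element_span=element_span,
        element_length=e_len,
        orf_record=orf_rec,
        orf_contig_span=orf_contig_span,
        integrity=integrity,
        motif=motif_hit,
        partition=partition,
        env=env_arch,
        verdict=verdict,
        polyprotein=orf_rec.protein if orf_rec else "",
        gc_hit_span=gc_hit_span,
    )


def _verdict(ltr_class, integrity, env_arch, pair, orf_rec) -> str:
    phlebo = env_arch is not None and env_arch.env_class == "phlebovirus_like_GN_GC"
    if integrity == "complete" and phlebo and ltr_class == "intact":
        return "intact_EVE_phlebovirus_env"
    if integrity == "complete":
        return "complete_polyprotein_other_env"
    if (pair is not None and pair.found) or orf_rec is not None:
        return "incomplete"
    return "rejected"


def run_screen(
    contigs: list[GenomeRecord],
    queries: list[ProteinRecord],
    config: ScreenConfig | None = None,
) -> list[EveCandidate]:
    """Full screen: seed loci with every query, analyze each locus, sort by
    (contig, start). An element-free genome returns an empty list."""
    config = config or ScreenConfig()
    matrix = load_blosum62()
    gn_queries, gc_queries = split_queries(queries)
    gn_ids = {q.id for q in gn_queries}

    all_hits: list[search.AlignmentHit] = []
    for q in queries:
        hits = search.scan_genome(
            contigs, q, matrix,
            gap_open=config.gap_open, gap_extend=config.gap_extend,
            min_bits=config.min_bits, min_aligned=config.min_aligned,
            merge_gap=config.merge_gap,
            lam=config.karlin_lambda, k=config.karlin_k,
        )
        logger.info("stage=search query=%s hits=%d", q.id, len(hits))
        all_hits.extend(hits)

    candidates = []
    loci = _cluster_loci(all_hits, config.merge_gap)
    for contig in contigs:
        for group in loci.get(contig.id, []):
            lo = min(h.t_start for h in group)
            hi = max(h.t_end for h in group)
            # orient flanks: on minus-frame loci the element 5' end lies at
            # higher contig coordinates
            plus = sum(h.raw_score for h in group if h.frame > 0) >= sum(
                h.raw_score for h in group if h.frame < 0
            )
            left = config.flank_upstream if plus else config.flank_downstream
            right = config.flank_downstream if plus else config.flank_upstream
            locus_start = max(1, lo - left)
            locus_end = min(contig.length, hi + right)
            locus_id = f"{contig.id}:{locus_start}-{locus_end}"
            candidates.append(
                analyze_locus(
                    contig, locus_start, locus_end, group, gn_ids, config, locus_id
                )
            )
    candidates.sort(key=lambda c: (c.contig, c.locus_span[0]))
    return candidates


def validate_locus(
    locus: GenomeRecord,
    queries: list[ProteinRecord],
    config: ScreenConfig | None = None,
) -> EveCandidate:
    """Single-locus mode: the same evidence chain without genome seeding."""
    config = config or ScreenConfig()
    matrix = load_blosum62()
    gn_ids = {q.id for q in split_queries(queries)[0]}
    hits: list[search.AlignmentHit] = []
    for q in queries:
        hits.extend(
            search.scan_genome(
                locus, q, matrix,
                gap_open=config.gap_open, gap_extend=config.gap_extend,
                min_bits=config.min_bits, min_aligned=config.min_aligned,
                merge_gap=config.merge_gap,
                lam=config.karlin_lambda, k=config.karlin_k,
            )
        )
    return analyze_locus(
        locus, 1, locus.length, hits, gn_ids, config, locus_id=locus.id
    )


def candidate_features(candidates: list[EveCandidate]) -> list[FeatureRecord]:
    """GFF3 features (nucleotide coordinates) for every candidate."""
    feats: list[FeatureRecord] = []
    for c in candidates:
        offset = c.locus_span[0] - 1
        if c.element_span:
            feats.append(
                FeatureRecord(
                    c.contig, c.element_span[0], c.element_span[1], "+", "element",
                    {"ID": c.locus_id, "verdict": c.verdict},
                )
            )
        if c.ltr_pair and c.ltr_pair.found:
            for which, span in (("ltr5", c.ltr_pair.ltr5), ("ltr3", c.ltr_pair.ltr3)):
                feats.append(
                    FeatureRecord(
                        c.contig, offset + span[0], offset + span[1], "+", "LTR",
                        {
                            "Parent": c.locus_id, "which": which,
                            "identity": f"{c.ltr_pair.identity:.2f}",
                            "class": c.ltr_class,
                        },
                    )
                )
        if c.orf_record and c.orf_contig_span:
            strand = c.orf_record.strand
            cs, ce = c.orf_contig_span
            feats.append(
                FeatureRecord(
                    c.contig, cs, ce, strand, "ORF",
                    {"Parent": c.locus_id, "residues": str(c.orf_record.translated_length),
                     "integrity": c.integrity},
                )
            )
            if c.motif and c.motif.motif:
                m1, m2 = _residue_to_nt(
                    c.motif.position, c.motif.position + 3, cs, ce - 3, strand
                )
                feats.append(
                    FeatureRecord(
                        c.contig, m1, m2, strand, "motif",
                        {"Parent": c.locus_id, "motif": c.motif.motif,
                         "variant": c.motif.variant},
                    )
                )
            if c.env:
                for t in c.env.tm_segments:
                    n1, n2 = _residue_to_nt(t.start, t.end, cs, ce - 3, strand)
                    feats.append(
                        FeatureRecord(c.contig, n1, n2, strand, "TM",
                                      {"Parent": c.locus_id}))
                for s in c.env.sequons:
                    n1, n2 = _residue_to_nt(s.position, s.position + 2, cs, ce - 3, strand)
                    feats.append(
                        FeatureRecord(c.contig, n1, n2, strand, "sequon",
                                      {"Parent": c.locus_id, "triplet": s.triplet}))
                for ftype, span in (("GN_region", c.env.gn_span),
                                    ("GC_region", c.env.gc_span)):
                    if span:
                        n1, n2 = _residue_to_nt(span[0], span[1], cs, ce - 3, strand)
                        feats.append(
                            FeatureRecord(c.contig, n1, n2, strand, ftype,
                                          {"Parent": c.locus_id}))
    return feats


def write_candidates_json(candidates: list[EveCandidate], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.as_json() for c in candidates], fh, indent=2)
        fh.write("\n")


def match_candidates_to_truth(candidates, truths) -> list[dict]:
    """Pair each planted truth with the overlapping candidate (if any) and
    report expected vs observed verdicts. Planted loci with no overlapping
    candidate are scored as verdict 'rejected' (the screen dismissed them)."""
    out = []
    for t in truths:
        hit = None
        for c in candidates:
            if c.contig != t.contig:
                continue
            span = c.element_span or c.locus_span
            if span[0] <= t.element_end and t.element_start <= span[1]:
                hit = c
                break
        out.append(
            {
                "locus_id": t.locus_id,
                "disruption": t.disruption,
                "expected": t.expected_verdict,
                "observed": hit.verdict if hit else "rejected",
                "candidate": hit,
                "truth": t,
                "match": (hit.verdict if hit else "rejected") == t.expected_verdict,
            }
        )
    return out
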