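"""Translated homology search: Smith-Waterman and PSSM scanning.

This re-implements the seeding step of the screen as an exact (non-heuristic)
local alignment of protein queries against all six reading frames of a
genome, plus a second-iteration position-specific scoring matrix (PSSM)
scan built from a seed alignment. E-values are deliberately not computed:
they depend on the size of the database searched, so raw scores are
normalized to bits with the Karlin-Altschul map and thresholded on bit
score and aligned length instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .scoring import (
    PROTEIN_ALPHABET,
    ScoringMatrix,
    background_vector,
    encode_protein,
    load_blosum62,
    profile_from_sequence,
)
from .seqio import GenomeRecord, ProteinRecord, frame_to_genome, six_frame_translations

#: default gapped Karlin-Altschul constants for BLOSUM62, gap 11/1
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

#: locus-seeding thresholds (replace database-dependent E-value cutoffs)
DEFAULT_MIN_BITS = 50.0
DEFAULT_MIN_ALIGNED = 80
DEFAULT_MERGE_GAP = 1000

_SCAN_CHUNK = 20000  # residues of frame translation per DP block
_MASK_CODE = 21


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a protein query (or PSSM) and a genome frame.

    Nucleotide coordinates are 1-based inclusive on the forward strand;
    frame is +1..+3 / -1..-3. For protein-vs-protein alignments frame is 0
    and the target span is in residues.
    """

    query_id: str
    target_id: str
    frame: int
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    raw_score: float
    bit_score: float
    pct_identity: float
    q_aln: str = ""
    t_aln: str = ""

    @property
    def aligned_length(self) -> int:
        return len(self.q_aln)


@dataclass
class PSSM:
    """Position-specific scoring matrix in half-bit units.

    scores: (L, 20) over PROTEIN_ALPHABET[:20]; built from a seed alignment
    with matrix-derived pseudocounts. Columns of the seed alignment with
    more than 50% gap characters are dropped from the model.
    """

    scores: np.ndarray
    source_id: str = "pssm"
    pseudocount: float = 1.0
    kept_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must have shape (L, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM entries must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def to_profile(self) -> np.ndarray:
        """(L, 22) kernel profile: X scores 0, mask symbol prohibitive."""
        prof = np.zeros((self.length, 22), dtype=np.float32)
        prof[:, :20] = self.scores
        prof[:, 20] = 0.0
        prof[:, 21] = -1e9
        return prof

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(PROTEIN_ALPHABET[:20]) + "\n")
            for i, row in enumerate(self.scores, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "PSSM":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[1:] != list(PROTEIN_ALPHABET[:20]):
                raise ValueError(f"{path}: unexpected PSSM header")
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in cols[1:]])
        return cls(scores=np.array(rows, dtype=np.float64), source_id=str(path))


def bit_score(raw: float, lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    """Karlin-Altschul normalized score: (lambda*raw - ln K) / ln 2."""
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    return (lam * raw - math.log(k)) / math.log(2)


def min_raw_for_bits(bits: float, lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    return (bits * math.log(2) + math.log(k)) / lam


def _identity(q_aln: str, t_aln: str) -> float:
    if not q_aln:
        return 0.0
    matches = sum(1 for a, b in zip(q_aln, t_aln) if a == b and a != "-")
    return 100.0 * matches / len(q_aln)


def _align_profile_local(
    prof: np.ndarray,
    query_letters: str,
    target_letters: str,
    t_codes: np.ndarray,
    gap_open: float,
    gap_extend: float,
):
    """Best local alignment of a profile against coded target; None if no
    positive-scoring path exists."""
    H, E, F = _kernels.sw_fill(prof, t_codes, np.float32(gap_open), np.float32(gap_extend))
    flat = int(np.argmax(H))
    i0, j0 = divmod(flat, H.shape[1])
    score = float(H[i0, j0])
    if score <= 0.0:
        return None
    q_idx, t_idx, n = _kernels.sw_traceback(
        H, E, F, prof, t_codes, np.float32(gap_open), np.float32(gap_extend), i0, j0
    )
    q_aln = "".join(
        "-" if q < 0 else (query_letters[q] if query_letters else "X") for q in q_idx
    )
    t_aln = "".join("-" if t < 0 else target_letters[t] for t in t_idx)
    qs = int(min(q for q in q_idx if q >= 0)) + 1
    qe = int(max(q for q in q_idx if q >= 0)) + 1
    ts = int(min(t for t in t_idx if t >= 0)) + 1
    te = int(max(t for t in t_idx if t >= 0)) + 1
    return score, qs, qe, ts, te, q_aln, t_aln


def smith_waterman(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: ScoringMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> AlignmentHit:
    """Optimal local alignment of two proteins under affine gaps.

    Returns a zero-score hit with empty alignment when no positive-scoring
    path exists (including empty inputs).
    """
    if gap_extend <= 0 or gap_open < gap_extend:
        raise ValueError("require gap_open >= gap_extend > 0")
    a_id, a_seq = (a.id, a.seq) if isinstance(a, ProteinRecord) else ("query", a)
    b_id, b_seq = (b.id, b.seq) if isinstance(b, ProteinRecord) else ("target", b)
    matrix = matrix or load_blosum62()
    empty = AlignmentHit(
        query_id=a_id, target_id=b_id, frame=0,
        t_start=0, t_end=0, q_start=0, q_end=0,
        raw_score=0.0, bit_score=bit_score(0.0, lam, k), pct_identity=0.0,
    )
    if not a_seq or not b_seq:
        return empty
    prof = profile_from_sequence(a_seq, matrix)
    res = _align_profile_local(prof, a_seq, b_seq, encode_protein(b_seq), gap_open, gap_extend)
    if res is None:
        return empty
    score, qs, qe, ts, te, q_aln, t_aln = res
    return AlignmentHit(
        query_id=a_id, target_id=b_id, frame=0,
        t_start=ts, t_end=te, q_start=qs, q_end=qe,
        raw_score=score, bit_score=bit_score(score, lam, k),
        pct_identity=_identity(q_aln, t_aln), q_aln=q_aln, t_aln=t_aln,
    )


def build_pssm(
    seed_alignment: list[str],
    pseudocount: float = 1.0,
    matrix: ScoringMatrix | None = None,
    source_id: str = "pssm",
) -> PSSM:
    """Per-column log-odds model (half-bit units) from an aligned seed set.

    Pseudocounts are matrix-derived: the pseudocount distribution for a
    column is sum_r f_r * P(a|r) with P(a|r) = p_a * 2^(s_ar/2), so a
    single-row alignment with a large pseudocount recovers the background
    substitution scores of that row's residues.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    L = len(seed_alignment[0])
    if any(len(row) != L for row in seed_alignment):
        raise ValueError("ragged seed alignment")
    matrix = matrix or load_blosum62()
    bg = background_vector()[:20]
    # conditional substitution probabilities implied by the half-bit matrix
    cond = bg[None, :] * np.power(2.0, matrix.scores[:20, :20].astype(np.float64) / 2.0)
    cond /= cond.sum(axis=1, keepdims=True)

    idx = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET[:20])}
    nrows = len(seed_alignment)
    scores = []
    kept = []
    for col in range(L):
        residues = [row[col] for row in seed_alignment]
        gaps = sum(1 for r in residues if r in "-.")
        if gaps * 2 > nrows:
            continue
        counts = np.zeros(20, dtype=np.float64)
        for r in residues:
            i = idx.get(r)
            if i is not None:
                counts[i] += 1.0
            elif r not in "-.":
                counts += bg  # X or nonstandard: spread as background
        n_obs = counts.sum()
        if n_obs == 0:
            continue
        freqs = counts / n_obs
        pc = freqs @ cond
        adj = (n_obs * freqs + pseudocount * pc) / (n_obs + pseudocount)
        scores.append(2.0 * np.log2(adj / bg))
        kept.append(col)
    if not scores:
        raise ValueError("no usable columns in seed alignment")
    return PSSM(
        scores=np.array(scores), source_id=source_id,
        pseudocount=pseudocount, kept_columns=kept,
    )


def _scan_frame(
    prof: np.ndarray,
    q_letters: str,
    frame_seq: str,
    min_raw: float,
    gap_open: float,
    gap_extend: float,
    max_hits: int = 50,
):
    """All disjoint local alignments scoring >= min_raw in one frame
    translation, found by iterative best-hit masking, chunked to bound
    memory."""
    L = prof.shape[0]
    n = len(frame_seq)
    overlap = min(n, 2 * L)
    step = max(_SCAN_CHUNK, 2 * overlap)
    hits = []
    start = 0
    while start < n:
        end = min(n, start + step + overlap)
        codes = encode_protein(frame_seq[start:end]).copy()
        letters = frame_seq[start:end]
        for _ in range(max_hits):
            res = _align_profile_local(prof, q_letters, letters, codes, gap_open, gap_extend)
            if res is None or res[0] < min_raw:
                break
            score, qs, qe, ts, te, q_aln, t_aln = res
            hits.append((score, qs, qe, start + ts, start + te, q_aln, t_aln))
            codes[ts - 1 : te] = _MASK_CODE
        if end == n:
            break
        start += step
    # de-duplicate overlap-region hits (same target span)
    seen = set()
    uniq = []
    for h in sorted(hits, key=lambda h: -h[0]):
        key = (h[3], h[4])
        if any(not (h[4] < s or h[3] > e) for s, e in seen):
            continue
        seen.add(key)
        uniq.append(h)
    return uniq


def scan_genome(
    genome: list[GenomeRecord] | GenomeRecord,
    query: ProteinRecord | PSSM,
    matrix: ScoringMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_bits: float = DEFAULT_MIN_BITS,
    min_aligned: int = DEFAULT_MIN_ALIGNED,
    merge_gap: int = DEFAULT_MERGE_GAP,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> list[AlignmentHit]:
    """Search all six frames of every contig with a protein query or PSSM.

    Same-contig, same-frame hits separated by at most merge_gap nucleotides
    are merged into one locus (the envelope cassette may align in pieces).
    Hits are sorted by bit score descending, ties by (contig, start).
    """
    if isinstance(genome, GenomeRecord):
        genome = [genome]
    matrix = matrix or load_blosum62()
    if isinstance(query, PSSM):
        prof = query.to_profile()
        q_letters = "X" * query.length
        q_id = query.source_id
    else:
        prof = profile_from_sequence(query.seq, matrix)
        q_letters = query.seq
        q_id = query.id
    min_raw = min_raw_for_bits(min_bits, lam, k)

    raw_hits: list[AlignmentHit] = []
    for contig in genome:
        frames = six_frame_translations(contig)
        for frame, fseq in frames.items():
            if len(fseq) == 0:
                continue
            for score, qs, qe, ts, te, q_aln, t_aln in _scan_frame(
                prof, q_letters, fseq, min_raw, gap_open, gap_extend
            ):
                g_start, g_end = frame_to_genome(frame, ts, te, contig.length)
                raw_hits.append(
                    AlignmentHit(
                        query_id=q_id, target_id=contig.id, frame=frame,
                        t_start=g_start, t_end=g_end, q_start=qs, q_end=qe,
                        raw_score=score, bit_score=bit_score(score, lam, k),
                        pct_identity=_identity(q_aln, t_aln),
                        q_aln=q_aln, t_aln=t_aln,
                    )
                )
    merged = merge_hits(raw_hits, merge_gap=merge_gap)
    kept = [h for h in merged if h.bit_score >= min_bits and (h.q_end - h.q_start + 1) >= min_aligned]
    kept.sort(key=lambda h: (-h.bit_score, h.target_id, h.t_start))
    return kept


def merge_hits(hits: list[AlignmentHit], merge_gap: int = DEFAULT_MERGE_GAP) -> list[AlignmentHit]:
    """Merge same-contig same-frame hits whose nucleotide gap is <= merge_gap.

    The merged locus takes the union span, summed raw score capped identity
    (score-weighted mean), and the best sub-hit's alignment strings.
    """
    by_group: dict[tuple[str, int, str], list[AlignmentHit]] = {}
    for h in hits:
        by_group.setdefault((h.target_id, h.frame, h.query_id), []).append(h)
    out = []
    for group in by_group.values():
        group.sort(key=lambda h: h.t_start)
        cluster: list[AlignmentHit] = []
        for h in group:
            if cluster and h.t_start - cluster[-1].t_end - 1 <= merge_gap:
                cluster.append(h)
            else:
                if cluster:
                    out.append(_merge_cluster(cluster))
                cluster = [h]
        if cluster:
            out.append(_merge_cluster(cluster))
    return out


def _merge_cluster(cluster: list[AlignmentHit]) -> AlignmentHit:
    if len(cluster) == 1:
        return cluster[0]
    best = max(cluster, key=lambda h: h.raw_score)
    total_raw = sum(h.raw_score for h in cluster)
    wid = sum(h.pct_identity * h.raw_score for h in cluster) / total_raw
    return AlignmentHit(
        query_id=best.query_id, target_id=best.target_id, frame=best.frame,
        t_start=min(h.t_start for h in cluster),
        t_end=max(h.t_end for h in cluster),
        q_start=min(h.q_start for h in cluster),
        q_end=max(h.q_end for h in cluster),
        raw_score=total_raw, bit_score=bit_score(total_raw),
        pct_identity=wid, q_aln=best.q_aln, t_aln=best.t_aln,
    )
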