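"""Detection and classification of the terminal direct repeats of an element.

A locus (homology seed plus flanks) is screened for a long terminal repeat
pair by local alignment of its first and last flank windows. Identity is
reported over aligned columns including gaps — the conservative convention
of common identity matrices. Classification distinguishes intact pairs
(identity at or above a threshold), degenerate pairs, repeats truncated by
a contig end, solo repeats (a single copy with no partner, detectable only
against a known repeat sequence), and absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from . import _kernels
from .scoring import dna_matrix, encode_nucleotide, profile_from_nucleotide

DEFAULT_FLANK_WINDOW = 3000
DEFAULT_MIN_LEN = 100
DEFAULT_MAX_LEN = 1500
DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -3.0
DEFAULT_GAP_OPEN = 5.0
DEFAULT_GAP_EXTEND = 2.0
DEFAULT_MIN_SCORE = 100.0
DEFAULT_INTACT_IDENTITY = 95.0
#: shortest repeat alignment worth keeping at all (candidate for "truncated")
MIN_PARTIAL_LEN = 30
#: how close (nt) a repeat end must be to a contig end to call truncation
DEFAULT_END_TOLERANCE = 20


@dataclass
class LtrPair:
    """A candidate terminal-repeat pair in locus coordinates (1-based).

    found is True when any repeat alignment of >= MIN_PARTIAL_LEN columns
    at >= min_score exists; classification is filled by classify().
    """

    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    length: int
    identity: float
    score: float
    aligned_columns: int
    found: bool
    classification: str = "none"
    q_aln: str = ""
    t_aln: str = ""


@dataclass
class IdentityMatrix:
    """Pairwise percent-identity over a set of repeat sequences."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("identity matrix must be square and symmetric")


def find_ltr_pair(
    locus_seq: str,
    flank_window: int = DEFAULT_FLANK_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_score: float = DEFAULT_MIN_SCORE,
) -> LtrPair:
    """Best local alignment between the first and last flank_window nt.

    Returns classification "none" (via found=False) when no alignment of at
    least MIN_PARTIAL_LEN columns reaches min_score; sub-min_len repeats are
    still reported so classify() can recognize assembly-truncated copies.
    """
    n = len(locus_seq)
    if n <= 2 * min_len:
        raise ValueError(f"locus ({n} nt) shorter than twice min_len ({min_len})")
    if not (min_len <= max_len <= flank_window):
        raise ValueError("require min_len <= max_len <= flank_window")
    w = min(flank_window, n // 2)
    head = locus_seq[:w]
    tail = locus_seq[n - w :]
    prof = profile_from_nucleotide(head, dna_matrix(match, mismatch))
    H, E, F = _kernels.sw_fill(
        prof, encode_nucleotide(tail), np.float32(gap_open), np.float32(gap_extend)
    )
    flat = int(np.argmax(H))
    i0, j0 = divmod(flat, H.shape[1])
    score = float(H[i0, j0])
    empty = LtrPair(
        ltr5=None, ltr3=None, length=0, identity=0.0,
        score=score, aligned_columns=0, found=False,
    )
    if score < min_score:
        return empty
    q_idx, t_idx, cols = _kernels.sw_traceback(
        H, E, F, prof, encode_nucleotide(tail),
        np.float32(gap_open), np.float32(gap_extend), i0, j0,
    )
    if cols < MIN_PARTIAL_LEN:
        return empty
    q_pos = [q for q in q_idx if q >= 0]
    t_pos = [t for t in t_idx if t >= 0]
    matches = sum(
        1
        for q, t in zip(q_idx, t_idx)
        if q >= 0 and t >= 0 and head[q] == tail[t]
    )
    ltr5 = (int(min(q_pos)) + 1, int(max(q_pos)) + 1)
    ltr3 = (n - w + int(min(t_pos)) + 1, n - w + int(max(t_pos)) + 1)
    if ltr5[1] >= ltr3[0]:
        return empty  # windows overlap and the "pair" is one region
    identity = 100.0 * matches / cols
    length = max(ltr5[1] - ltr5[0] + 1, ltr3[1] - ltr3[0] + 1)
    pair = LtrPair(
        ltr5=ltr5, ltr3=ltr3, length=length, identity=identity,
        score=score, aligned_columns=cols, found=True,
        q_aln="".join("-" if q < 0 else head[q] for q in q_idx),
        t_aln="".join("-" if t < 0 else tail[t] for t in t_idx),
    )
    if not (min_len <= cols <= max_len):
        pair.classification = "none"
    return pair


def _global_identity(a: str, b: str, match=DEFAULT_MATCH, mismatch=DEFAULT_MISMATCH,
                     gap_open=DEFAULT_GAP_OPEN, gap_extend=DEFAULT_GAP_EXTEND) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns if columns else 100.0


def identity_matrix(repeats: list[str], labels: list[str] | None = None) -> IdentityMatrix:
    """Pairwise global-alignment identity (percent over aligned columns,
    gaps included in the denominator)."""
    if len(repeats) < 2:
        raise ValueError("need at least two sequences")
    n = len(repeats)
    labels = labels or [f"seq{i+1}" for i in range(n)]
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = _global_identity(repeats[i], repeats[j])
    return IdentityMatrix(labels=labels, values=vals)


def classify(
    pair: LtrPair,
    locus_offset: int = 0,
    contig_length: int | None = None,
    locus_seq: str | None = None,
    known_ltr: str | None = None,
    intact_threshold: float = DEFAULT_INTACT_IDENTITY,
    min_len: int = DEFAULT_MIN_LEN,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> str:
    """Assign {intact, degenerate, truncated, solo, none} to a repeat pair.

    locus_offset is the 0-based contig position of the locus start, so
    contig-end adjacency can be checked for truncation calls. Solo detection
    needs a known repeat sequence to search for the single copy.
    """
    if pair.found:
        if pair.aligned_columns >= min_len:
            cls = "intact" if pair.identity >= intact_threshold else "degenerate"
        elif contig_length is not None and _abuts_end(
            pair, locus_offset, contig_length, end_tolerance
        ):
            cls = "truncated"
        else:
            cls = "none"
    elif known_ltr is not None and locus_seq is not None:
        cls = "solo" if _has_single_copy(locus_seq, known_ltr, min_len) else "none"
    else:
        cls = "none"
    pair.classification = cls
    return cls


def _abuts_end(pair: LtrPair, offset: int, contig_length: int, tol: int) -> bool:
    ltr5_contig_start = offset + pair.ltr5[0]
    ltr3_contig_end = offset + pair.ltr3[1]
    return ltr5_contig_start <= tol + 1 or ltr3_contig_end >= contig_length - tol


def _has_single_copy(locus_seq: str, known_ltr: str, min_len: int) -> bool:
    prof = profile_from_nucleotide(known_ltr, dna_matrix())
    codes = encode_nucleotide(locus_seq).copy()
    go, ge = np.float32(DEFAULT_GAP_OPEN), np.float32(DEFAULT_GAP_EXTEND)
    copies = 0
    for _ in range(3):
        H, E, F = _kernels.sw_fill(prof, codes, go, ge)
        flat = int(np.argmax(H))
        i0, j0 = divmod(flat, H.shape[1])
        if float(H[i0, j0]) < 1.2 * min_len:  # ~60% identity over min_len
            break
        q_idx, t_idx, cols = _kernels.sw_traceback(H, E, F, prof, codes, go, ge, i0, j0)
        if cols < min_len:
            break
        copies += 1
        t_pos = [t for t in t_idx if t >= 0]
        codes[min(t_pos) : max(t_pos) + 1] = 5  # mask
    return copies == 1


def delimit_element(pair: LtrPair) -> tuple[tuple[int, int], int]:
    """Element span (first nt of the 5' repeat to last nt of the 3' repeat,
    locus coordinates) and its length. Requires an intact or degenerate pair."""
    if pair.classification not in {"intact", "degenerate"}:
        raise ValueError(
            f"cannot delimit an element from a {pair.classification!r} repeat pair"
        )
    span = (pair.ltr5[0], pair.ltr3[1])
    return span, span[1] - span[0] + 1
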