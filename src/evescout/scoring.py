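"""Substitution matrices and alphabet encodings shared by the aligners.

Protein scoring uses a BLOSUM62-class matrix (half-bit log-odds) with the
community-default affine gap penalties (open 11, extend 1): a gap of length k
costs open + (k-1)*extend. Nucleotide scoring for terminal-repeat detection
defaults to match +2 / mismatch -3 with gap open 5 / extend 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

#: canonical residue order used by every kernel; X absorbs unknowns.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
#: final slot is a mask symbol with prohibitive scores (used to excise hits).
MASK_CODE_PROTEIN = len(PROTEIN_ALPHABET)

NUC_ALPHABET_ORDER = "ACGTN"
MASK_CODE_NUC = len(NUC_ALPHABET_ORDER)

#: BLOSUM62 marginal (background) residue frequencies, standard published values.
BLOSUM62_BACKGROUND = {
    "A": 0.0742, "R": 0.0520, "N": 0.0446, "D": 0.0536, "C": 0.0247,
    "Q": 0.0342, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0247, "F": 0.0474, "P": 0.0387,
    "S": 0.0573, "T": 0.0508, "W": 0.0132, "Y": 0.0324, "V": 0.0729,
}

_PROT_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
_NUC_INDEX = {nt: i for i, nt in enumerate(NUC_ALPHABET_ORDER)}


@dataclass(frozen=True)
class ScoringMatrix:
    """A symmetric residue substitution matrix over PROTEIN_ALPHABET.

    scores has shape (21, 21); expected score under the background must be
    negative for local-alignment statistics to be meaningful.
    """

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (21, 21):
            raise ValueError("protein matrix must be 21x21 (20 residues + X)")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[_PROT_INDEX.get(a, 20), _PROT_INDEX.get(b, 20)])


def load_blosum62() -> ScoringMatrix:
    """The standard BLOSUM62 matrix, reindexed to PROTEIN_ALPHABET."""
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.float32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            mat[i, j] = raw[a, b]
    return ScoringMatrix(name="BLOSUM62", scores=mat)


def dna_matrix(match: float = 2.0, mismatch: float = -3.0) -> np.ndarray:
    """5x5 nucleotide matrix over ACGTN; N scores as mismatch against anything."""
    mat = np.full((5, 5), mismatch, dtype=np.float32)
    for i in range(4):
        mat[i, i] = match
    mat[4, :] = mismatch
    mat[:, 4] = mismatch
    return mat


def encode_protein(seq: str) -> np.ndarray:
    return np.fromiter((_PROT_INDEX.get(c, 20) for c in seq), dtype=np.int8, count=len(seq))


def encode_nucleotide(seq: str) -> np.ndarray:
    return np.fromiter((_NUC_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def profile_from_sequence(seq: str, matrix: ScoringMatrix) -> np.ndarray:
    """Position x symbol score profile for a plain protein query.

    Shape (L, 22): one column per PROTEIN_ALPHABET symbol plus the mask
    symbol (prohibitively negative), so the same DP kernel serves plain
    queries and PSSMs.
    """
    codes = encode_protein(seq)
    prof = np.empty((len(seq), 22), dtype=np.float32)
    prof[:, :21] = matrix.scores[codes]
    prof[:, 21] = -1e9
    return prof


def profile_from_nucleotide(seq: str, matrix: np.ndarray) -> np.ndarray:
    """Position x symbol profile for a nucleotide query (shape (L, 6))."""
    codes = encode_nucleotide(seq)
    prof = np.empty((len(seq), 6), dtype=np.float32)
    prof[:, :5] = matrix[codes]
    prof[:, 5] = -1e9
    return prof


def background_vector() -> np.ndarray:
    """Background frequencies in PROTEIN_ALPHABET order (X gets a tiny mass)."""
    vec = np.array(
        [BLOSUM62_BACKGROUND[aa] for aa in PROTEIN_ALPHABET[:20]] + [1e-4],
        dtype=np.float64,
    )
    return vec / vec.sum()
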