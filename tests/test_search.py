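"""Local alignment, PSSM construction, and genome scanning."""

import math

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from evescout import search, synth
from evescout.scoring import load_blosum62
from evescout.seqio import GenomeRecord, ProteinRecord, revcomp

AA = "ARNDCQEGHILKMFPSTWYV"


def reference_aligner(gap_open=11, gap_extend=1):
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -gap_open
    a.extend_gap_score = -gap_extend
    return a


def brute_force_local(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Exhaustive enumeration of every local alignment path with affine gap
    runs. Exponential; only for tiny strings."""
    best = 0.0

    def rec(i, j, state, score):
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "Y", score - (gap_extend if state == "Y" else gap_open))
        if j < len(b):
            rec(i, j + 1, "X", score - (gap_extend if state == "X" else gap_open))

    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            rec(i, j, "M", 0.0)
    return best


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self):
        m = load_blosum62()
        s = "MKWVLLIAGQ"
        hit = search.smith_waterman(s, s, m)
        assert hit.raw_score == sum(m.score(c, c) for c in s)
        assert hit.pct_identity == 100.0
        assert (hit.q_start, hit.q_end) == (1, len(s))

    def test_empty_sequence_scores_zero(self):
        hit = search.smith_waterman("", "MKWV")
        assert hit.raw_score == 0.0 and hit.q_aln == ""

    def test_matches_exhaustive_enumeration_tiny(self):
        m = load_blosum62()
        rng = np.random.default_rng(0)
        for _ in range(40):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 5)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 5)))
            assert search.smith_waterman(a, b, m).raw_score == pytest.approx(
                brute_force_local(a, b, m, 11.0, 1.0)
            ), (a, b)

    @pytest.mark.parametrize("gaps", [(11.0, 1.0), (5.0, 2.0)])
    def test_matches_independent_aligner(self, gaps):
        go, ge = gaps
        ref = reference_aligner(go, ge)
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 8)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 8)))
            mine = search.smith_waterman(a, b, gap_open=go, gap_extend=ge).raw_score
            assert mine == pytest.approx(ref.score(a, b)), (a, b)

    def test_symmetry_and_reversal_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=10))
            b = "".join(rng.choice(list(AA), size=12))
            s_ab = search.smith_waterman(a, b).raw_score
            assert s_ab == search.smith_waterman(b, a).raw_score
            assert s_ab == search.smith_waterman(a[::-1], b[::-1]).raw_score

    def test_gap_parameter_validation(self):
        with pytest.raises(ValueError):
            search.smith_waterman("MK", "MK", gap_open=1.0, gap_extend=2.0)


class TestBitScore:
    def test_formula(self):
        assert search.bit_score(0, 0.267, 0.041) == pytest.approx(
            -math.log(0.041) / math.log(2), abs=1e-9
        )
        assert search.bit_score(0, 0.267, 0.041) == pytest.approx(4.61, abs=0.01)

    def test_zero_point(self):
        raw = math.log(0.041) / 0.267
        assert search.bit_score(raw) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_increasing(self):
        scores = [search.bit_score(r) for r in range(0, 200, 10)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            search.bit_score(10, -1, 0.041)


class TestPssm:
    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            search.build_pssm(["MKW", "MK"])

    def test_row_order_invariance(self):
        rows = ["MKWV", "MRWV", "MKWI"]
        p1 = search.build_pssm(rows, 0.5)
        p2 = search.build_pssm(rows[::-1], 0.5)
        assert np.allclose(p1.scores, p2.scores)

    def test_conserved_column_is_positive_mode(self):
        p = search.build_pssm(["K" * 5] * 8, pseudocount=0.01)
        from evescout.scoring import PROTEIN_ALPHABET

        k = PROTEIN_ALPHABET.index("K")
        assert (p.scores[:, k] > 0).all()
        assert (p.scores.argmax(axis=1) == k).all()

    def test_large_pseudocount_limit_is_matrix_row(self):
        """One row + huge pseudocount: log-odds collapse to the background
        substitution scores of the observed residue (closed form)."""
        m = load_blosum62()
        p = search.build_pssm(["WKA"], pseudocount=1e7)
        from evescout.scoring import PROTEIN_ALPHABET

        for row, res in zip(p.scores, "WKA"):
            for j, other in enumerate(PROTEIN_ALPHABET[:20]):
                assert row[j] == pytest.approx(m.score(res, other), abs=0.5)

    def test_majority_gap_columns_dropped(self):
        p = search.build_pssm(["M-KV", "M-RV", "MG-V"], 0.5)
        assert p.length == 3  # column 2 (>50% gaps) dropped
        assert p.kept_columns == [0, 2, 3]

    def test_tsv_round_trip(self, tmp_path):
        p = search.build_pssm(["MKWV", "MRWV"], 0.5)
        path = tmp_path / "m.pssm.tsv"
        p.write_tsv(path)
        back = search.PSSM.read_tsv(path)
        assert np.allclose(p.scores, back.scores, atol=1e-4)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    poly, _ = synth.random_polyprotein(600, seed=rng)
    cassette = poly[250:500]
    nt = synth.back_translate(cassette, seed=rng)[:-3]
    bg = synth.generate_background(60_000, seed=rng).seq
    genome = GenomeRecord("ctg", bg[:30_000] + nt + bg[30_000:])
    return genome, ProteinRecord("q", cassette)


class TestScanGenome:
    def test_planted_self_hit(self, planted):
        genome, query = planted
        hits = search.scan_genome(genome, query)
        assert hits, "planted cassette not found"
        top = hits[0]
        assert top.pct_identity == 100.0
        assert (top.t_start, top.t_end) == (30_001, 30_000 + 3 * len(query.seq))
        assert top.frame == 1

    def test_strand_symmetry(self, planted):
        genome, query = planted
        fwd = search.scan_genome(genome, query)[0]
        rc = search.scan_genome(
            GenomeRecord("rc", revcomp(genome.seq)), query
        )[0]
        assert rc.raw_score == fwd.raw_score
        assert rc.frame < 0
        L = genome.length
        assert (rc.t_start, rc.t_end) == (L - fwd.t_end + 1, L - fwd.t_start + 1)

    def test_shuffled_query_yields_no_hits(self):
        """Empirical null: a decoy query finds nothing above threshold in
        element-free background (three seeds at 10^5 nt)."""
        rng = np.random.default_rng(6)
        poly, _ = synth.random_polyprotein(400, seed=rng)
        decoy = "".join(rng.permutation(list(poly[:300])))
        for seed in (101, 102, 103):
            bg = synth.generate_background(100_000, seed=seed)
            assert search.scan_genome(bg, ProteinRecord("decoy", decoy)) == []

    def test_merge_hits_bridges_split_alignments(self):
        h = dict(query_id="q", target_id="c", frame=1, q_start=1, q_end=50,
                 raw_score=100.0, bit_score=search.bit_score(100.0),
                 pct_identity=90.0, q_aln="A", t_aln="A")
        a = search.AlignmentHit(**{**h, "t_start": 1000, "t_end": 1150})
        b = search.AlignmentHit(**{**h, "t_start": 1900, "t_end": 2050})
        c = search.AlignmentHit(**{**h, "t_start": 9000, "t_end": 9150})
        merged = search.merge_hits([a, b, c], merge_gap=1000)
        spans = sorted((m.t_start, m.t_end) for m in merged)
        assert spans == [(1000, 2050), (9000, 9150)]
        assert max(m.raw_score for m in merged) == 200.0
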