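"""Terminal-repeat detection, identity matrices, and classification."""

import numpy as np
import pytest

from evescout import ltr, synth
from evescout.seqio import revcomp
from evescout.synth import EveSpec, assemble_eve, generate_background


def planted_locus(divergence=0.0, seed=1, flank=1200):
    """An element with known repeats embedded in background, plus its truth."""
    elem, truth = assemble_eve(EveSpec(ltr_divergence=divergence), seed=seed)
    rng = np.random.default_rng(seed + 1000)
    left = generate_background(flank, seed=rng).seq
    right = generate_background(flank, seed=rng).seq
    bout = synth.BOUNDARY_BLOCK_OUT
    locus = left[: -len(bout)] + bout + elem + bout + right[len(bout):]
    return locus, elem, truth, flank


class TestFindPair:
    def test_planted_identical_repeats_found_exactly(self):
        locus, elem, truth, flank = planted_locus(0.0, seed=3)
        pair = ltr.find_ltr_pair(locus, flank_window=1500)
        assert pair.found
        assert pair.length == 271
        assert pair.identity == 100.0
        assert pair.ltr5 == (flank + 1, flank + 271)
        assert pair.ltr3 == (flank + len(elem) - 270, flank + len(elem))

    def test_five_mutations_give_counting_identity(self):
        """Mutate 5 interior sites of the 3' repeat: identity 266/271."""
        locus, elem, truth, flank = planted_locus(0.0, seed=4)
        l3_start = flank + len(elem) - 271
        chars = list(locus)
        for pos in (20, 60, 100, 150, 200):
            i = l3_start + pos
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        pair = ltr.find_ltr_pair("".join(chars), flank_window=1500)
        assert pair.aligned_columns == 271
        assert pair.identity == pytest.approx(100 * 266 / 271)

    def test_short_locus_rejected(self):
        with pytest.raises(ValueError):
            ltr.find_ltr_pair("ACGT" * 40, min_len=100)

    def test_no_repeat_in_random_sequence(self):
        g = generate_background(4000, seed=5)
        pair = ltr.find_ltr_pair(g.seq, flank_window=1500)
        assert not pair.found

    def test_revcomp_invariance(self):
        locus, elem, truth, flank = planted_locus(0.02, seed=6)
        n = len(locus)
        p1 = ltr.find_ltr_pair(locus, flank_window=1500)
        p2 = ltr.find_ltr_pair(revcomp(locus), flank_window=1500)
        assert p2.found
        assert p2.aligned_columns == p1.aligned_columns
        assert p2.identity == pytest.approx(p1.identity)
        # the 5' repeat of the reverse complement mirrors the 3' repeat
        assert p2.ltr5 == (n - p1.ltr3[1] + 1, n - p1.ltr3[0] + 1)
        assert p2.ltr3 == (n - p1.ltr5[1] + 1, n - p1.ltr5[0] + 1)

    def test_detected_identity_equals_identity_matrix_of_repeats(self):
        locus, elem, truth, flank = planted_locus(0.05, seed=7)
        pair = ltr.find_ltr_pair(locus, flank_window=1500)
        r5 = locus[pair.ltr5[0] - 1 : pair.ltr5[1]]
        r3 = locus[pair.ltr3[0] - 1 : pair.ltr3[1]]
        im = ltr.identity_matrix([r5, r3])
        assert pair.identity == pytest.approx(im.values[0, 1])

    def test_divergence_grid_tracks_expected_identity(self):
        """Mean detected identity decreases along a divergence grid and sits
        near 100*(1-d) (termini excepted) within Monte-Carlo error."""
        grid = (0.0, 0.05, 0.1, 0.15, 0.2)
        means = []
        for d in grid:
            idents = []
            for seed in range(8):
                locus, _, _, _ = planted_locus(d, seed=100 + seed)
                pair = ltr.find_ltr_pair(locus, flank_window=1500)
                assert pair.found
                idents.append(pair.identity)
            means.append(np.mean(idents))
        assert all(a >= b for a, b in zip(means, means[1:]))
        for d, m in zip(grid, means):
            expected = 100 * (1 - d) * (267 / 271) + 100 * (4 / 271)
            assert m == pytest.approx(expected, abs=2.0)


class TestIdentityMatrix:
    def test_identical_sequences(self):
        im = ltr.identity_matrix(["ACGTACGT", "ACGTACGT"])
        assert im.values[0, 1] == 100.0

    def test_symmetric_with_unit_diagonal(self):
        seqs = [generate_background(120, seed=s).seq for s in range(4)]
        im = ltr.identity_matrix(seqs)
        assert np.allclose(im.values, im.values.T)
        assert np.allclose(np.diag(im.values), 100.0)

    def test_counting_oracle_substitutions_only(self):
        base = generate_background(200, seed=9).seq
        mutant, realized = synth.mutate(base, 0.08, seed=10)
        k = round((100.0 - realized) * 2)  # mismatched sites
        im = ltr.identity_matrix([base, mutant])
        assert im.values[0, 1] == pytest.approx(100 * (200 - k) / 200)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ltr.identity_matrix([])


class TestClassify:
    def test_intact_and_degenerate_threshold(self):
        locus, _, _, _ = planted_locus(0.0, seed=11)
        pair = ltr.find_ltr_pair(locus, flank_window=1500)
        assert ltr.classify(pair) == "intact"
        locus2, _, _, _ = planted_locus(0.15, seed=12)
        pair2 = ltr.find_ltr_pair(locus2, flank_window=1500)
        assert ltr.classify(pair2) == "degenerate"

    def test_truncated_at_contig_end(self):
        elem, truth = assemble_eve(EveSpec(disruption="ltr_truncation"), seed=13)
        bg = generate_background(800, seed=14).seq  # 5' repeat inside the window
        contig = bg[:-8] + synth.BOUNDARY_BLOCK_OUT + elem  # element ends the contig
        pair = ltr.find_ltr_pair(contig, flank_window=1500)
        assert pair.found and pair.aligned_columns < 100
        cls = ltr.classify(pair, locus_offset=0, contig_length=len(contig))
        assert cls == "truncated"

    def test_solo_with_known_repeat(self):
        elem, truth = assemble_eve(
            EveSpec(orf_length=0, disruption="solo_ltr"), seed=15
        )
        bg = generate_background(4000, seed=16).seq
        locus = bg[:2000] + elem + bg[2000:]
        pair = ltr.find_ltr_pair(locus, flank_window=1500)
        assert not pair.found
        cls = ltr.classify(pair, locus_seq=locus, known_ltr=elem)
        assert cls == "solo"

    def test_none_without_evidence(self):
        g = generate_background(4000, seed=17)
        pair = ltr.find_ltr_pair(g.seq, flank_window=1500)
        assert ltr.classify(pair) == "none"


class TestDelimit:
    def test_additivity_for_planted_pair(self):
        locus, elem, truth, flank = planted_locus(0.0, seed=18)
        pair = ltr.find_ltr_pair(locus, flank_window=1500)
        ltr.classify(pair)
        span, length = ltr.delimit_element(pair)
        assert length == len(elem) == 2 * 271 + (len(elem) - 542)
        assert span == (flank + 1, flank + len(elem))

    def test_requires_bracketing_classification(self):
        g = generate_background(4000, seed=19)
        pair = ltr.find_ltr_pair(g.seq, flank_window=1500)
        ltr.classify(pair)
        with pytest.raises(ValueError):
            ltr.delimit_element(pair)
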