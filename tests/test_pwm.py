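"""Match-style PWM scoring and promoter scanning."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import miregnet as m
from miregnet.pwm import reverse_complement
from oracles import brute_force_best_window_score

BASES = "ACGT"


def _pwm_from_freqs(rows, name="X"):
    return m.PositionWeightMatrix(name, np.asarray(rows, dtype=float))


@st.composite
def random_count_matrices(draw):
    length = draw(st.integers(5, 10))
    rows = draw(st.lists(
        st.lists(st.integers(0, 30), min_size=4, max_size=4).filter(
            lambda r: sum(r) > 0 and sorted(r)[-1] != sorted(r)[-2]
        ),
        min_size=length, max_size=length,
    ))
    return m.PositionWeightMatrix.from_counts("RAND", np.asarray(rows))


class TestInformationVector:
    def test_uniform_position_is_zero(self):
        pwm = _pwm_from_freqs([[0.25] * 4] * 4)
        assert np.allclose(pwm.information, 0.0)

    def test_degenerate_position_is_ln4(self):
        pwm = _pwm_from_freqs([[1, 0, 0, 0]] + [[0.25] * 4] * 3)
        assert pwm.information[0] == pytest.approx(math.log(4), abs=1e-12)

    def test_half_half_position_is_ln2(self):
        pwm = _pwm_from_freqs([[0.5, 0.5, 0, 0]] + [[0.25] * 4] * 3)
        assert pwm.information[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_non_negative(self, toy_pwm):
        assert np.all(toy_pwm.information >= 0)


class TestMatrixSimilarity:
    def test_consensus_scores_one(self, toy_pwm):
        assert m.matrix_similarity(toy_pwm, toy_pwm.consensus) == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self, toy_pwm):
        assert m.matrix_similarity(toy_pwm, toy_pwm.anti_consensus) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self, toy_pwm):
        with pytest.raises(m.ContractError):
            m.matrix_similarity(toy_pwm, "ACGT")

    def test_exhaustive_windows_on_toy_matrix(self):
        # every 4-mer: scores in [0,1], max attained exactly at consensus,
        # and each value equals the hand-normalized hand-summed score
        pwm = m.PositionWeightMatrix.from_counts(
            "T4", np.array([[12, 1, 1, 1], [1, 14, 2, 0],
                            [0, 1, 1, 18], [9, 3, 2, 1]]))
        freqs = pwm.frequencies.tolist()
        smin = brute_force_best_window_score(
            freqs, [min(range(4), key=row.__getitem__) for row in freqs])
        smax = brute_force_best_window_score(
            freqs, [max(range(4), key=row.__getitem__) for row in freqs])
        best = []
        for window in map("".join, product(BASES, repeat=4)):
            mss = m.matrix_similarity(pwm, window)
            assert 0.0 <= mss <= 1.0
            raw = brute_force_best_window_score(
                freqs, [BASES.index(b) for b in window])
            assert mss == pytest.approx((raw - smin) / (smax - smin), abs=1e-9)
            best.append((mss, window))
        assert max(best) == (pytest.approx(1.0), pwm.consensus)

    @settings(derandomize=True, max_examples=40)
    @given(random_count_matrices())
    def test_consensus_scores_one_on_random_matrices(self, pwm):
        assert m.matrix_similarity(pwm, pwm.consensus) == pytest.approx(1.0)
        assert m.core_similarity(pwm, pwm.consensus) == pytest.approx(1.0)


class TestCoreSimilarity:
    def test_core_is_most_informative_block(self):
        # informative block at positions 3..7; uniform elsewhere
        rows = [[0.25] * 4] * 3 + [[1, 0, 0, 0]] * 5 + [[0.25] * 4] * 2
        pwm = _pwm_from_freqs(rows)
        assert pwm.core_start == 3

    def test_core_match_with_weak_flanks(self):
        rows = [[0.4, 0.3, 0.2, 0.1]] + [[1, 0, 0, 0]] * 5 + [[0.4, 0.3, 0.2, 0.1]]
        pwm = _pwm_from_freqs(rows)
        window = "T" + "A" * 5 + "T"  # consensus core, worst flanks
        assert m.core_similarity(pwm, window) == pytest.approx(1.0)
        assert m.matrix_similarity(pwm, window) < 1.0

    def test_uniform_matrix_css_is_one(self):
        pwm = _pwm_from_freqs([[0.25] * 4] * 6)
        for window in ("ACGTAC", "TTTTTT"):
            assert m.core_similarity(pwm, window) == 1.0
            assert m.matrix_similarity(pwm, window) == 1.0

    def test_short_matrix_degenerates_to_mss(self):
        pwm = _pwm_from_freqs([[0.7, 0.1, 0.1, 0.1]] * 4)
        for window in ("ACGT", "AAAA", "TTTT"):
            assert m.core_similarity(pwm, window) == pytest.approx(
                m.matrix_similarity(pwm, window))

    def test_leftmost_tie_break(self):
        rows = [[1, 0, 0, 0]] * 7  # all positions equally informative
        assert _pwm_from_freqs(rows).core_start == 0


class TestScanPromoter:
    def test_planted_consensus_recovered(self, toy_pwm):
        import random
        rng = random.Random(11)
        seq = [rng.choice(BASES) for _ in range(1000)]
        seq[37:37 + toy_pwm.length] = toy_pwm.consensus
        hits = m.scan_promoter(m.PromoterSequence("PTEN", "".join(seq)), toy_pwm)
        exact = [h for h in hits if h.start == 37 and h.strand == "+"]
        assert len(exact) == 1 and exact[0].mss == pytest.approx(1.0)

    def test_all_n_sequence_yields_nothing(self, toy_pwm):
        hits = m.scan_promoter(m.PromoterSequence("X", "N" * 1000), toy_pwm)
        assert hits == []

    def test_sequence_shorter_than_matrix(self, toy_pwm):
        hits = m.scan_promoter(m.PromoterSequence("X", "ACGT"), toy_pwm)
        assert hits == []

    def test_palindromic_consensus_hits_both_strands(self):
        pal = m.PositionWeightMatrix.from_counts(
            "PAL", np.array([[20, 0, 0, 0], [0, 0, 20, 0],
                             [0, 20, 0, 0], [0, 0, 0, 20]]))
        assert reverse_complement(pal.consensus) == pal.consensus
        seq = "T" * 100 + pal.consensus + "T" * 96
        hits = m.scan_promoter(m.PromoterSequence("X", seq), pal, 0.95, 0.95)
        assert {(h.start, h.strand) for h in hits} == {(100, "+"), (100, "-")}

    def test_minus_strand_site_reported_in_plus_coordinates(self, toy_pwm):
        site = reverse_complement(toy_pwm.consensus)
        seq = "C" * 200 + site + "C" * (800 - len(site))
        hits = m.scan_promoter(m.PromoterSequence("X", seq), toy_pwm, 0.95, 0.95)
        assert any(h.start == 200 and h.strand == "-" and
                   h.mss == pytest.approx(1.0) for h in hits)

    def test_hits_sorted_and_deterministic(self, toy_pwm):
        proms, _ = m.generate_promoters([toy_pwm], 5, plant_rate=1.0, seed=2)
        for prom in proms:
            hits = m.scan_promoter(prom, toy_pwm)
            assert hits == sorted(hits, key=lambda h: (h.start, h.strand))
            assert hits == m.scan_promoter(prom, toy_pwm)

    def test_cutoff_monotonicity(self, toy_pwm):
        proms, _ = m.generate_promoters([toy_pwm], 10, plant_rate=0.5, seed=9)
        base = len(m.scan_promoters(proms, [toy_pwm], 0.5, 0.5))
        for css, mss in [(0.6, 0.5), (0.5, 0.6), (0.8, 0.8), (1.0, 1.0)]:
            assert len(m.scan_promoters(proms, [toy_pwm], css, mss)) <= base

    def test_strand_symmetry(self, toy_pwm):
        proms, _ = m.generate_promoters([toy_pwm], 5, plant_rate=1.0, seed=4)
        rc_pwm = toy_pwm.reverse_complement()
        for prom in proms:
            fwd = m.scan_promoter(prom, toy_pwm, 0.7, 0.8)
            rc_prom = m.PromoterSequence(prom.gene,
                                         reverse_complement(prom.sequence))
            mirrored = m.scan_promoter(rc_prom, rc_pwm, 0.7, 0.8)
            n = len(prom.sequence)
            L = toy_pwm.length
            # coordinates mirror; the strand label is relative to the given
            # sequence and carries over unchanged
            expect = {(n - L - h.start, h.strand, round(h.mss, 9),
                       round(h.css, 9)) for h in fwd}
            got = {(h.start, h.strand, round(h.mss, 9), round(h.css, 9))
                   for h in mirrored}
            assert got == expect


class TestPredictedTfSet:
    def test_distinct_tfs(self):
        hits = [m.BindingSiteHit("NFKB1", "PTEN", 10, "+", 0.9, 0.95),
                m.BindingSiteHit("NFKB1", "FHIT", 4, "-", 0.8, 0.9)]
        assert m.predicted_tf_set(hits) == {"NFKB1"}

    def test_empty(self):
        assert m.predicted_tf_set([]) == set()

    def test_owner_restriction(self):
        hits = [m.BindingSiteHit("NFKB1", "PTEN", 10, "+", 0.9, 0.95),
                m.BindingSiteHit("MYC", "OTHER", 4, "-", 0.8, 0.9)]
        assert m.predicted_tf_set(hits, promoter_owners={"PTEN"}) == {"NFKB1"}


class TestFormats:
    def test_transfac_round_trip(self, toy_pwm, tmp_path):
        path = tmp_path / "m.transfac"
        m.write_transfac([toy_pwm], path)
        back, = m.read_transfac(path)
        assert back.name == toy_pwm.name
        assert back.consensus == toy_pwm.consensus
        assert np.allclose(back.frequencies, toy_pwm.frequencies, atol=0.02)

    def test_counts_tsv(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("A\tC\tG\tT\n10\t0\t0\t0\n0\t10\t0\t0\n"
                        "0\t0\t10\t0\n0\t0\t0\t10\n")
        pwm = m.read_counts_tsv(path, name="T1")
        assert pwm.consensus == "ACGT" and pwm.length == 4

    def test_fasta_round_trip(self, toy_pwm, tmp_path):
        proms, _ = m.generate_promoters([toy_pwm], 3, plant_rate=1.0, seed=1)
        path = tmp_path / "p.fa"
        path.write_text("".join(f">{p.gene}\n{p.sequence}\n" for p in proms))
        back = m.read_promoters_fasta(path)
        assert [(p.gene, p.sequence) for p in back] == \
            [(p.gene, p.sequence) for p in proms]

    def test_bed_output(self, toy_pwm, tmp_path):
        hits = [m.BindingSiteHit("TOYTF", "PTEN", 37, "+", 0.9, 1.0)]
        out = tmp_path / "hits.bed"
        m.write_hits_bed(hits, [toy_pwm], out)
        assert out.read_text() == f"PTEN\t37\t{37 + toy_pwm.length}\tTOYTF\t1000\t+\n"
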