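"""PWM statistics, canonical k-mer indexing and signal-track scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mpba
from mpba.motifs import (
    all_kmer_class_count,
    kmer_from_index,
    matching_index_count,
    parse_iupac_pattern,
    pattern_in_kmer,
)


def pwm_from_columns(*cols, tf="tf"):
    return mpba.PWM(tf, np.array(cols, dtype=float).T)


def random_pwm(rng, length):
    return mpba.PWM("r", rng.dirichlet(np.ones(4), size=length).T)


class TestPWMValidation:
    def test_bad_column_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pwm_from_columns([0.5, 0.5, 0.5, 0.0])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_columns([1.2, -0.2, 0.0, 0.0])

    def test_reverse_complement_swaps_bases_and_reverses(self):
        pwm = pwm_from_columns([1, 0, 0, 0], [0, 1, 0, 0])  # columns A, C
        rc = pwm.reverse_complement()
        # revcomp of AC is GT: first column G, second column T
        assert rc.probs[2, 0] == 1 and rc.probs[3, 1] == 1


class TestInformationContent:
    @pytest.mark.parametrize("column, expected", [
        ((0.25, 0.25, 0.25, 0.25), 0.0),   # maximum entropy
        ((1.0, 0.0, 0.0, 0.0), 2.0),        # point mass
        ((0.5, 0.5, 0.0, 0.0), 1.0),        # hand evaluation of the formula
    ])
    def test_known_columns(self, column, expected):
        ic = mpba.column_information_content(pwm_from_columns(column))
        assert ic[0] == pytest.approx(expected, abs=1e-12)

    def test_bounded_on_random_pwms(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ic = mpba.column_information_content(random_pwm(rng, 8))
            assert np.all(ic >= -1e-12) and np.all(ic <= 2 + 1e-12)


class TestCentralVariablePosition:
    def test_unique_argmax_offset(self):
        cols = [[0.25] * 4] * 7
        cols[3] = [0.97, 0.01, 0.01, 0.01]
        pos = mpba.central_variable_position(
            pwm_from_columns(*cols), (10, 17)
        )
        assert pos == 13

    def test_all_tied_picks_middle(self):
        pwm = pwm_from_columns(*[[0.25] * 4] * 5)
        assert mpba.central_variable_position(pwm, (0, 5)) == 2

    def test_equidistant_tie_picks_leftmost(self):
        cols = [[0.25] * 4] * 5
        cols[1] = cols[3] = [0.7, 0.1, 0.1, 0.1]
        assert mpba.central_variable_position(
            pwm_from_columns(*cols), (0, 5)
        ) == 1

    def test_span_length_mismatch_raises(self):
        pwm = pwm_from_columns(*[[0.25] * 4] * 5)
        with pytest.raises(ValueError, match="does not match"):
            mpba.central_variable_position(pwm, (0, 6))


class TestHamming:
    @pytest.mark.parametrize("a, b, d", [
        ("AGGGG", "AGGGG", 0),
        ("AGGGT", "AGGGG", 1),
        ("CCCCC", "AGGGG", 5),
    ])
    def test_known_distances(self, a, b, d):
        assert mpba.hamming_to_canonical(a, b) == d

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            mpba.hamming_to_canonical("AGG", "AGGG")


class TestPWMDistance:
    def test_single_column_point_masses(self):
        a = pwm_from_columns([1, 0, 0, 0])
        b = pwm_from_columns([0, 1, 0, 0])
        assert mpba.pwm_euclidean_distance(a, b) == pytest.approx(np.sqrt(2))

    @given(st.integers(0, 10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (random_pwm(rng, 5) for _ in range(3))
        dab = mpba.pwm_euclidean_distance(a, b)
        dba = mpba.pwm_euclidean_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-12)
        assert mpba.pwm_euclidean_distance(a, a) == 0.0
        assert dab <= (
            mpba.pwm_euclidean_distance(a, c)
            + mpba.pwm_euclidean_distance(c, b)
            + 1e-12
        )

    def test_sliding_alignment_of_unequal_lengths(self):
        rng = np.random.default_rng(3)
        long_ = random_pwm(rng, 8)
        short = mpba.PWM("s", long_.probs[:, 2:6])
        # the shorter PWM is an exact sub-matrix: minimum distance is 0
        assert mpba.pwm_euclidean_distance(long_, short) == 0.0
        assert mpba.pwm_euclidean_distance(short, long_) == 0.0


class TestCanonicalKmerIndex:
    def test_reverse_complement_pairs_share_index(self):
        assert mpba.canonical_kmer_index("AAAAAAA") == \
            mpba.canonical_kmer_index("TTTTTTT")
        assert mpba.canonical_kmer_index("ACGTACG") == \
            mpba.canonical_kmer_index("CGTACGT")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            mpba.canonical_kmer_index("ACGTANG")

    def test_class_count_odd_k_small(self):
        # brute-force enumeration for k=3: 64 k-mers, no palindromes -> 32
        assert all_kmer_class_count(k=3) == 32

    @given(st.integers(0, 4 ** 7 - 1))
    def test_index_is_revcomp_invariant(self, code):
        # decode the raw code directly (not necessarily canonical)
        from mpba.motifs import _decode
        kmer = _decode(code, 7)
        idx = mpba.canonical_kmer_index(kmer)
        assert idx == mpba.canonical_kmer_index(mpba.reverse_complement(kmer))
        # the representative k-mer of the class maps back to the same index
        assert mpba.canonical_kmer_index(kmer_from_index(idx, 7)) == idx


class TestIupacPatterns:
    def test_bracket_group_equivalent_to_iupac(self):
        assert parse_iupac_pattern("GAATG[CT]") == parse_iupac_pattern("GAATGY")

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            parse_iupac_pattern("GAAT*G")

    def test_match_searches_both_strands(self):
        # TGAAAC on the reverse strand of GTTTCAG
        assert pattern_in_kmer("GTTTCAG", "TGAAAC")
        assert not pattern_in_kmer("CCCCCCC", "TGAAAC")

    def test_min_length_enforced(self):
        with pytest.raises(ValueError):
            mpba.MotifPattern("x", "ACG")


def make_track(values, sequence, start=0, chrom="chrI"):
    return mpba.SignalTrack(
        chrom=chrom, start=start, values=np.asarray(values, float),
        sequence=sequence,
    )


class TestKmerScores:
    def test_constant_track_scores_constant(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        track = make_track(np.full(80, 3.5), seq)
        promoters = mpba.PromoterSet([("chrI", 15, 65)])
        scores = mpba.kmer_relative_binding_scores(track, promoters)
        assert scores
        assert all(v == pytest.approx(3.5) for v in scores.values())

    def test_single_occurrence_single_index(self):
        seq = "C" * 15 + "AAAAAAA" + "C" * 18
        track = make_track(np.ones(len(seq)), seq)
        promoters = mpba.PromoterSet([("chrI", 15, 22)])
        scores = mpba.kmer_relative_binding_scores(track, promoters)
        assert set(scores) == {mpba.canonical_kmer_index("AAAAAAA")}

    def test_planted_kmer_scores_highest(self):
        rng = np.random.default_rng(5)
        target = "GATTACA"
        blocks = []
        for _ in range(6):
            blocks.append("".join(rng.choice(list("ACGT"), size=30)))
            blocks.append(target)
        seq = "C" * 15 + "".join(blocks) + "C" * 15
        values = np.ones(len(seq))
        idx_t = mpba.canonical_kmer_index(target)
        for pos in range(15, len(seq) - 7 + 1):
            if mpba.canonical_kmer_index(seq[pos:pos + 7]) == idx_t:
                mid = pos + 3
                values[mid - 10:mid + 10] = 10.0
        track = make_track(values, seq)
        promoters = mpba.PromoterSet([("chrI", 15, len(seq) - 15)])
        scores = mpba.kmer_relative_binding_scores(track, promoters)
        top = max(scores, key=scores.get)
        assert top == idx_t

    def test_edge_windows_skipped(self):
        # promoter flush with the track: 7-mers whose 20 bp window exits
        # the track must be skipped, not scored
        seq = "A" * 30
        track = make_track(np.ones(30), seq)
        promoters = mpba.PromoterSet([("chrI", 0, 30)])
        scores = mpba.kmer_relative_binding_scores(track, promoters)
        # midpoints needing [mid-10, mid+10) inside [0, 30): mid in [10, 20]
        assert set(scores) == {mpba.canonical_kmer_index("A" * 7)}

    def test_requires_sequence(self):
        track = mpba.SignalTrack("chrI", 0, np.ones(30))
        with pytest.raises(ValueError, match="sequence"):
            mpba.kmer_relative_binding_scores(
                track, mpba.PromoterSet([("chrI", 0, 30)])
            )


class TestMotifEnrichment:
    def test_uniform_scores_give_unity(self):
        kmers = ["TGAAACA", "CCCCCCC", "GGGGAGG", "ACGTACG"]
        scores = {mpba.canonical_kmer_index(k): 2.0 for k in kmers}
        assert mpba.motif_enrichment(scores, "TGAAAC") == pytest.approx(1.0)

    def test_three_index_toy_ratio(self):
        scores = {
            mpba.canonical_kmer_index("TGAAACA"): 2.0,
            mpba.canonical_kmer_index("CCCCCCC"): 1.0,
            mpba.canonical_kmer_index("GGGGAGG"): 1.0,
        }
        # mean(matching)=2, mean(all)=4/3 -> 1.5
        assert mpba.motif_enrichment(scores, "TGAAAC") == pytest.approx(1.5)
        assert matching_index_count(scores, "TGAAAC") == 1

    def test_doubled_matching_scores_enrich(self):
        rng = np.random.default_rng(2)
        scores = {}
        for _ in range(50):
            k = "".join(rng.choice(list("ACGT"), size=7))
            scores[mpba.canonical_kmer_index(k)] = (
                2.0 if pattern_in_kmer(k, "GAATG[CT]") else 1.0
            )
        scores[mpba.canonical_kmer_index("GAATGCA")] = 2.0
        assert mpba.motif_enrichment(scores, "GAATG[CT]") > 1.0

    def test_no_match_raises(self):
        scores = {mpba.canonical_kmer_index("CCCCCCC"): 1.0}
        with pytest.raises(ValueError, match="no scored"):
            mpba.motif_enrichment(scores, "TGAAAC")


class TestPromoterZscoreCount:
    def make_matrix(self, n_outliers=0):
        # 11 promoters so a single-outlier column reaches |z| = sqrt(10) > 3
        idx = [f"p{i}" for i in range(11)]
        data = {}
        for t in range(5):
            base = np.linspace(1.0, 2.0, 11) + 0.1 * t
            if t < n_outliers:
                base = np.zeros(11)
                base[0] = 50.0
            data[f"TF{t}"] = base
        return pd.DataFrame(data, index=idx)

    def test_no_outliers_counts_zero(self):
        assert mpba.promoter_zscore_tf_count(self.make_matrix(), "p0") == 0

    def test_single_extreme_tf(self):
        assert mpba.promoter_zscore_tf_count(self.make_matrix(1), "p0") == 1

    def test_three_planted_outliers(self):
        m = self.make_matrix(3)
        assert mpba.promoter_zscore_tf_count(m, "p0") == 3
        assert mpba.promoter_zscore_tf_count(m, "p5") == 0

    def test_zero_variance_column_warned_and_excluded(self):
        m = self.make_matrix(1)
        m["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            assert mpba.promoter_zscore_tf_count(m, "p0") == 1


def test_pattern_matching_consistent_with_enumeration():
    # brute-force oracle: expand GAATG[CT] into its two literal 6-mers and
    # check pattern_in_kmer against substring search over both strands
    literals = {"GAATGC", "GAATGT"}
    rng = np.random.default_rng(9)
    for _ in range(200):
        k = "".join(rng.choice(list("ACGT"), size=7))
        expect = any(
            lit in s for lit in literals
            for s in (k, mpba.reverse_complement(k))
        )
        assert pattern_in_kmer(k, "GAATG[CT]") == expect
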