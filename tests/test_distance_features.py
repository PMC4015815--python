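"""Distance-pair feature construction against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from distsvm.distance_features import (
    DistanceFeatureVector,
    build_feature_vector,
    count_distance_block,
    dr_features,
    dt_features,
    feature_index,
    read_sparse_features,
    vector_length,
    write_sparse_features,
)
from distsvm.profile_io import (
    ALPHABET_INDEX,
    FrequencyProfile,
    ProteinSequence,
    SymbolSequence,
    read_pssm,
    symbols_from_string,
)

from conftest import naive_feature_vector


def _idx(letter: str) -> int:
    return ALPHABET_INDEX[letter]


class TestFeatureIndex:
    def test_unigram_block_comes_first(self):
        assert feature_index("unigram", 0) == 0
        assert feature_index("unigram", 19) == 19

    def test_first_pair_feature_follows_unigrams(self):
        assert feature_index("pair", 0, 0, d=1) == 20

    @pytest.mark.parametrize("d_max", [1, 2, 150])
    def test_last_pair_feature_matches_dimension_formula(self, d_max):
        assert feature_index("pair", 19, 19, d=d_max) == 20 + 400 * d_max - 1

    def test_bijection_over_full_layout(self):
        d_max = 3
        seen = set()
        for a in range(20):
            seen.add(feature_index("unigram", a))
        for d in range(1, d_max + 1):
            for a in range(20):
                for b in range(20):
                    seen.add(feature_index("pair", a, b, d=d))
        assert seen == set(range(vector_length(d_max)))

    @pytest.mark.parametrize(
        "kind,args",
        [
            ("unigram", dict(first=20)),
            ("unigram", dict(first=0, d=1)),
            ("pair", dict(first=0, second=None, d=1)),
            ("pair", dict(first=0, second=20, d=1)),
            ("pair", dict(first=0, second=0, d=0)),
            ("spam", dict(first=0)),
        ],
    )
    def test_invalid_arguments(self, kind, args):
        with pytest.raises(ValueError):
            feature_index(kind, **args)


class TestCountDistanceBlock:
    def test_kffk_adjacent_pairs(self):
        s = symbols_from_string("s", "KFFK")
        block = count_distance_block(s, 1)
        K, F = _idx("K"), _idx("F")
        expected = np.zeros((20, 20), dtype=int)
        expected[K, F] = 1
        expected[F, F] = 1
        expected[F, K] = 1
        assert np.array_equal(block, expected)

    def test_kffk_offset_two(self):
        s = symbols_from_string("s", "KFFK")
        block = count_distance_block(s, 2)
        K, F = _idx("K"), _idx("F")
        assert block[K, F] == 1 and block[F, K] == 1
        assert block.sum() == 2

    def test_offset_beyond_length_is_empty(self):
        s = symbols_from_string("s", "KFFK")
        assert count_distance_block(s, 4).sum() == 0
        assert count_distance_block(s, 10).sum() == 0

    def test_rejects_nonpositive_distance(self):
        s = symbols_from_string("s", "KFFK")
        with pytest.raises(ValueError):
            count_distance_block(s, 0)


class TestBuildFeatureVector:
    def test_worked_example_kffk_dmax2(self):
        """The 4-residue worked example: length 820, 7 nonzeros, total 9."""
        s = symbols_from_string("s", "KFFK")
        v = build_feature_vector(s, 2)
        assert len(v) == 820
        assert np.count_nonzero(v.values) == 7
        assert v.values.sum() == 9
        K, F = _idx("K"), _idx("F")
        assert v.values[K] == 2 and v.values[F] == 2
        assert v.values[feature_index("pair", K, F, d=1)] == 1
        assert v.values[feature_index("pair", F, F, d=1)] == 1
        assert v.values[feature_index("pair", F, K, d=1)] == 1
        assert v.values[feature_index("pair", K, F, d=2)] == 1
        assert v.values[feature_index("pair", F, K, d=2)] == 1
        assert np.array_equal(v.values, naive_feature_vector(s.symbols, s.valid, 2))

    def test_dmax_zero_is_composition(self):
        s = symbols_from_string("s", "AAGV")
        v = build_feature_vector(s, 0)
        assert len(v) == 20
        assert v.values[_idx("A")] == 2
        assert v.values[_idx("G")] == 1
        assert v.values[_idx("V")] == 1

    def test_single_symbol_no_pairs(self):
        v = build_feature_vector(symbols_from_string("s", "A"), 5)
        assert len(v) == 2020
        assert np.count_nonzero(v.values) == 1
        assert v.values[0] == 1

    @pytest.mark.parametrize("d_max", [0, 1, 5, 20])
    def test_oracle_equivalence_random_sequences(self, rng, d_max):
        """Exact integer agreement with the naive double loop, masked positions included."""
        for _ in range(50):
            L = int(rng.integers(2, 301))
            symbols = rng.integers(0, 20, size=L)
            valid = rng.random(L) > 0.1
            symbols = np.where(valid, symbols, -1)
            s = SymbolSequence(id="r", symbols=symbols, valid=valid)
            fast = build_feature_vector(s, d_max).values
            assert np.array_equal(fast, naive_feature_vector(symbols, valid, d_max))

    def test_conservation_for_fully_valid(self, rng):
        L, d_max = 57, 9
        s = SymbolSequence(
            id="c", symbols=rng.integers(0, 20, size=L), valid=np.ones(L, bool)
        )
        v = build_feature_vector(s, d_max)
        expected = L + sum(max(0, L - d) for d in range(1, d_max + 1))
        assert v.values.sum() == expected

    @given(st.integers(0, 2**31 - 1), st.integers(0, 12))
    @settings(max_examples=40, deadline=None)
    def test_monotone_nesting(self, seed, k):
        """F_k is an exact prefix of F_dmax for any k <= d_max."""
        r = np.random.default_rng(seed)
        d_max = k + int(r.integers(0, 5))
        L = int(r.integers(2, 60))
        s = SymbolSequence(
            id="n", symbols=r.integers(0, 20, size=L), valid=np.ones(L, bool)
        )
        full = build_feature_vector(s, d_max).values
        prefix = build_feature_vector(s, k).values
        assert np.array_equal(full[: 20 + 400 * k], prefix)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_prepend_never_decreases_counts(self, seed):
        r = np.random.default_rng(seed)
        L = int(r.integers(2, 50))
        symbols = r.integers(0, 20, size=L)
        s = SymbolSequence(id="a", symbols=symbols, valid=np.ones(L, bool))
        extended = SymbolSequence(
            id="b",
            symbols=np.concatenate(([int(r.integers(0, 20))], symbols)),
            valid=np.ones(L + 1, bool),
        )
        v0 = build_feature_vector(s, 6).values
        v1 = build_feature_vector(extended, 6).values
        assert np.all(v1 >= v0)

    def test_length_invariant_rejects_bad_vector(self):
        with pytest.raises(ValueError):
            DistanceFeatureVector(sequence_id="x", d_max=1, values=np.zeros(21))


class TestDrDtFeatures:
    def test_dr_worked_example_aglp(self):
        v = dr_features(ProteinSequence(id="p", residues="AGLP"), 2)
        A, G, L, P = (_idx(c) for c in "AGLP")
        nz = {int(i): int(x) for i, x in enumerate(v.values) if x}
        assert nz == {
            A: 1, G: 1, L: 1, P: 1,
            feature_index("pair", A, G, d=1): 1,
            feature_index("pair", G, L, d=1): 1,
            feature_index("pair", L, P, d=1): 1,
            feature_index("pair", A, L, d=2): 1,
            feature_index("pair", G, P, d=2): 1,
        }

    def test_dr_repeated_residue(self):
        v = dr_features(ProteinSequence(id="p", residues="AAAA"), 1)
        A = _idx("A")
        assert v.values[A] == 4
        assert v.values[feature_index("pair", A, A, d=1)] == 3
        assert v.values.sum() == 7

    def test_dr_masked_position_drops_spanning_pairs(self):
        v = dr_features(ProteinSequence(id="p", residues="AXGA"), 1)
        A, G = _idx("A"), _idx("G")
        nz = {int(i): int(x) for i, x in enumerate(v.values) if x}
        assert nz == {A: 2, G: 1, feature_index("pair", G, A, d=1): 1}

    def test_dt_worked_example_equals_kffk_vector(self, worked_example_pssm):
        profile = read_pssm(worked_example_pssm)
        v = dt_features(profile, 2)
        expected = build_feature_vector(symbols_from_string("s", "KFFK"), 2)
        assert np.array_equal(v.values, expected.values)

    def test_degenerate_profile_makes_dt_equal_dr(self, rng):
        from distsvm.synthetic_data import generate_null_sequence, synthetic_profile

        seq = generate_null_sequence(40, np.full(20, 0.05), rng, seq_id="s")
        profile = synthetic_profile(seq, 1.0, rng)
        assert np.array_equal(dt_features(profile, 4).values, dr_features(seq, 4).values)

    def test_operating_point_dimension(self):
        seq = ProteinSequence(id="p", residues="AGLP")
        assert len(dr_features(seq, 150)) == 60020


class TestSparseFeatureFile:
    def test_single_nonzero_line_format(self, tmp_path):
        v = DistanceFeatureVector(
            sequence_id="s1", d_max=0, values=np.array([2] + [0] * 19)
        )
        path = tmp_path / "f.svml"
        write_sparse_features([v], [1], path)
        line = path.read_text().splitlines()[0]
        assert line.startswith("+1 1:2")

    def test_empty_list_empty_file(self, tmp_path):
        path = tmp_path / "empty.svml"
        write_sparse_features([], [], path)
        assert path.read_text() == ""

    def test_round_trip(self, tmp_path, rng):
        vecs = []
        labels = []
        for i in range(5):
            s = SymbolSequence(
                id=f"s{i}", symbols=rng.integers(0, 20, 30), valid=np.ones(30, bool)
            )
            vecs.append(build_feature_vector(s, 3))
            labels.append(1 if i % 2 == 0 else -1)
        path = tmp_path / "rt.svml"
        write_sparse_features(vecs, labels, path)
        X, y, ids, d_max = read_sparse_features(path)
        assert d_max == 3
        assert ids == [f"s{i}" for i in range(5)]
        assert np.array_equal(y, np.array(labels))
        assert np.array_equal(X, np.stack([v.values for v in vecs]).astype(float))

    def test_inconsistent_dmax_rejected(self, tmp_path):
        v1 = DistanceFeatureVector("a", 1, np.zeros(420, dtype=int))
        v2 = DistanceFeatureVector("b", 2, np.zeros(820, dtype=int))
        with pytest.raises(ValueError, match="d_max"):
            write_sparse_features([v1, v2], [1, -1], tmp_path / "x.svml")
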