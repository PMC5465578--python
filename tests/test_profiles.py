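import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddisyn.profiles import (
    CATEGORY_ORDER,
    FeatureIndex,
    InteractionProfile,
    InteractionRecord,
    PairUniverse,
    ProfileError,
    ProfileMatrix,
    build_feature_index,
    canonical_pair,
    combine_confidences,
    combine_pair,
    encode_profile,
    encode_profile_matrix,
    filter_interactions,
    prune_features,
    read_interaction_tsv,
    read_profile_matrix,
    write_profile_matrix,
)


def rec(chem="d1", prot="P1", org="9606", cat="binding", conf=0.5):
    return InteractionRecord(chem, prot, org, cat, conf)


class TestCombineConfidences:
    @pytest.mark.parametrize(
        "sources, expected",
        [
            ([0.4], 0.4),          # single source passes through
            ([1.0, 0.2], 1.0),     # certainty absorbs
            ([0.5, 0.5], 0.75),    # 1 - 0.5 * 0.5
            ([0.2, 0.3, 0.5], 1 - 0.8 * 0.7 * 0.5),
        ],
    )
    def test_noisy_or_combination(self, sources, expected):
        assert combine_confidences(sources) == pytest.approx(expected)

    def test_rejects_out_of_range_and_empty(self):
        with pytest.raises(ValueError):
            combine_confidences([0.5, 1.2])
        with pytest.raises(ValueError):
            combine_confidences([-0.1])
        with pytest.raises(ValueError):
            combine_confidences([])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=5),
        st.floats(0, 1),
    )
    def test_monotone_in_each_source(self, sources, extra):
        base = combine_confidences(sources)
        assert combine_confidences(sources + [extra]) >= base - 1e-12
        assert 0.0 <= base <= 1.0


class TestFilterInteractions:
    def test_confidence_boundary_is_inclusive(self):
        records = [
            rec(conf=0.39),                      # below medium confidence: dropped
            rec(conf=0.40, cat="catalysis"),     # boundary: retained
            rec(conf=0.90, org="10090"),         # non-human: dropped
            rec(conf=0.90, cat="other"),         # unretained category: dropped
            rec(conf=0.90),
        ]
        kept = filter_interactions(records)
        assert kept == [records[1], records[4]]

    def test_idempotent_and_order_preserving(self):
        records = [rec(conf=c, prot=f"P{i}") for i, c in enumerate([0.9, 0.1, 0.5, 0.45])]
        once = filter_interactions(records)
        assert filter_interactions(once) == once
        assert [r.protein_id for r in once] == ["P0", "P2", "P3"]


class TestFeatureIndex:
    def test_four_slots_per_protein_in_bica_order(self):
        records = [rec(prot="P2"), rec(prot="P1", cat="catalysis")]
        index = build_feature_index(records)
        assert len(index) == 8
        assert index.features[:4] == tuple(("P1", c) for c in CATEGORY_ORDER)
        assert index.features[4:] == tuple(("P2", c) for c in CATEGORY_ORDER)

    def test_empty_and_scaling(self):
        assert len(build_feature_index([])) == 0
        many = [rec(prot=f"P{i:04d}") for i in range(2637)]
        assert len(build_feature_index(many)) == 10548

    def test_name_round_trip(self):
        index = build_feature_index([rec(prot="P1"), rec(prot="P9606.X")])
        assert FeatureIndex.from_names(index.feature_names()) == index


class TestEncodeProfile:
    def test_single_record_sets_the_right_slot(self):
        records = [rec(prot="P1", cat="activation")]
        index = build_feature_index(records)
        p = encode_profile("d1", records, index)
        assert p.popcount() == 1
        assert p.bits[index.position("P1", "activation")]

    def test_two_categories_same_protein_block(self):
        records = [rec(cat="binding"), rec(cat="inhibition")]
        index = build_feature_index(records)
        p = encode_profile("d1", records, index)
        assert p.popcount() == 2
        assert set(np.nonzero(p.bits)[0]) == {0, 1}

    def test_no_records_gives_all_zero(self):
        index = build_feature_index([rec()])
        assert encode_profile("other", [rec()], index).popcount() == 0

    def test_unknown_feature_raises(self):
        index = build_feature_index([rec(prot="P1")])
        with pytest.raises(ProfileError):
            encode_profile("d1", [rec(prot="P2")], index)


@st.composite
def bit_pairs(draw, length=16):
    a = draw(st.lists(st.booleans(), min_size=length, max_size=length))
    b = draw(st.lists(st.booleans(), min_size=length, max_size=length))
    return np.array(a), np.array(b)


class TestCombinePair:
    index16 = FeatureIndex([(f"P{i}", "binding") for i in range(16)])

    def profile(self, bits, name="d"):
        padded = np.zeros(16, dtype=bool)
        padded[: len(bits)] = bits
        return InteractionProfile(name, padded, self.index16)

    def test_or_semantics(self):
        p = combine_pair(
            self.profile([1, 0, 1, 0], "a"), self.profile([0, 1, 1, 0], "b")
        )
        assert p.bits[:4].astype(int).tolist() == [1, 1, 1, 0]

    def test_mismatched_index_raises(self):
        other = InteractionProfile(
            "x", np.zeros(4, bool), FeatureIndex([(f"Q{i}", "binding") for i in range(4)])
        )
        with pytest.raises(ProfileError):
            combine_pair(self.profile([1]), other)

    @settings(max_examples=100, derandomize=True)
    @given(bit_pairs())
    def test_or_is_commutative_idempotent_and_popcount_identity(self, bits):
        a, b = bits
        pa, pb = self.profile(a, "a"), self.profile(b, "b")
        ab = combine_pair(pa, pb)
        ba = combine_pair(pb, pa)
        assert np.array_equal(ab.bits, ba.bits)
        assert np.array_equal(combine_pair(pa, pa).bits, pa.bits)
        # inclusion-exclusion on popcounts
        assert ab.popcount() == pa.popcount() + pb.popcount() - int((a & b).sum())
        assert ab.popcount() >= max(pa.popcount(), pb.popcount())

    @settings(max_examples=50, derandomize=True)
    @given(bit_pairs(), st.lists(st.booleans(), min_size=16, max_size=16))
    def test_or_is_associative(self, bits, c):
        a, b = bits
        pa, pb, pc = self.profile(a, "a"), self.profile(b, "b"), self.profile(c, "c")
        left = combine_pair(combine_pair(pa, pb), pc)
        right = combine_pair(pa, combine_pair(pb, pc))
        assert np.array_equal(left.bits, right.bits)


class TestPruneFeatures:
    def test_drops_only_all_zero_columns(self, tiny_matrix):
        m = tiny_matrix.matrix.copy()
        m[:, [1, 5, 6]] = False
        mat = ProfileMatrix(tiny_matrix.row_ids, tiny_matrix.index, m)
        pruned = prune_features(mat)
        assert len(pruned.index) == int(m.any(axis=0).sum())
        assert pruned.matrix.any(axis=0).all()

    def test_identity_when_nothing_to_prune(self):
        index = FeatureIndex([("P1", "binding")])
        mat = ProfileMatrix(["d1"], index, np.ones((1, 1), bool))
        assert prune_features(mat) is mat

    def test_scores_preserved_under_any_weights(self, tiny_matrix):
        rng = np.random.default_rng(3)
        m = tiny_matrix.matrix.copy()
        m[:, [0, 7]] = False
        mat = ProfileMatrix(tiny_matrix.row_ids, tiny_matrix.index, m)
        pruned = prune_features(mat)
        w = rng.normal(size=len(mat.index))
        w_kept = np.array(
            [w[mat.index.position(*f)] for f in pruned.index.features]
        )
        assert np.allclose(mat.matrix @ w, pruned.matrix @ w_kept)


class TestPairUniverse:
    def test_handshake_count(self, tiny_matrix):
        u = PairUniverse.all_pairs(tiny_matrix)
        n = tiny_matrix.n_rows
        assert len(u) == n * (n - 1) // 2

    def test_pair_matrix_is_or_of_rows(self, tiny_matrix):
        u = PairUniverse.all_pairs(tiny_matrix)
        pm = u.pair_matrix()
        k = 17
        a, b = u.pairs[k]
        expected = tiny_matrix.row(a).bits | tiny_matrix.row(b).bits
        assert np.array_equal(pm.matrix[k], expected)

    def test_canonical_pair_is_order_free(self):
        assert canonical_pair("b", "a") == canonical_pair("a", "b") == ("a", "b")


class TestReadersWriters:
    def test_interaction_tsv_reader_filters_and_scales(self, tmp_path):
        path = tmp_path / "links.tsv"
        path.write_text(
            "chemical\tprotein\tmode\tcombined_score\n"
            "d1\t9606.P1\tbinding\t900\n"      # 0-1000 scale detected
            "d1\t9606.P2\tinhibition\t390\n"   # 0.39 -> dropped
            "d2\t10090.P1\tbinding\t800\n"     # mouse -> dropped
            "d2\t9606.P1\texpression\t999\n"   # unknown category -> dropped
            "d2\t9606.P1\tcatalysis\t400\n"    # boundary -> kept
        )
        records = read_interaction_tsv(path)
        assert [(r.chemical_id, r.protein_id, r.category, r.confidence) for r in records] == [
            ("d1", "P1", "binding", 0.9),
            ("d2", "P1", "catalysis", 0.4),
        ]

    def test_per_source_scores_are_combined(self, tmp_path):
        path = tmp_path / "links.tsv"
        path.write_text(
            "chemical\tprotein\tmode\tscore_text\tscore_exp\n"
            "d1\t9606.P1\tbinding\t0.5\t0.5\n"
        )
        (record,) = read_interaction_tsv(path)
        assert record.confidence == pytest.approx(0.75)

    def test_profile_matrix_round_trip(self, tmp_path, tiny_matrix):
        path = tmp_path / "profiles.tsv"
        write_profile_matrix(tiny_matrix, path)
        back = read_profile_matrix(path)
        assert back.row_ids == tiny_matrix.row_ids
        assert back.index == tiny_matrix.index
        assert np.array_equal(back.matrix, tiny_matrix.matrix)

    def test_drugs_without_retained_interactions_are_excluded(self):
        records = filter_interactions(
            [rec(chem="d1", prot="P1"), rec(chem="d2", prot="P2", conf=0.9)]
        )
        # d3 is known from the label table but all its records were filtered
        with pytest.warns(UserWarning, match="no retained"):
            m = encode_profile_matrix(records, drug_ids=["d1", "d2", "d3"])
        assert m.row_ids == ["d1", "d2"]
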