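import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hetmc import (
    AnnotationSets,
    AssociationMatrix,
    ExpressionMatrix,
    OntologyDag,
    SequenceSet,
    SimilarityMatrix,
    cosine_profile_similarity,
    expression_similarity,
    integrate,
    jaccard_similarity,
    lncrna_functional_similarity,
    semantic_similarity_dag,
    sequence_similarity,
    tune_weight_grid,
)
from oracles import (
    functional_similarity_bruteforce,
    gotoh_score,
    semantic_similarity_enumeration,
    spearman_abs,
)


def _assert_valid_similarity(S: SimilarityMatrix):
    assert np.abs(S.values - S.values.T).max() <= 1e-10
    assert S.values.min() >= 0.0 and S.values.max() <= 1.0


class TestJaccard:
    def test_hand_example(self):
        ann = AnnotationSets({"d1": {"a", "b", "c"}, "d2": {"b", "c", "d"}})
        S = jaccard_similarity(ann, ["d1", "d2"])
        assert S.values[0, 1] == 0.5  # 2 shared / 4 union

    def test_identical_and_disjoint_and_empty(self):
        ann = AnnotationSets({"x": {"a"}, "y": {"a"}, "z": {"b"}, "w": set()})
        S = jaccard_similarity(ann, ["x", "y", "z", "w"])
        assert S.values[0, 1] == 1.0
        assert S.values[0, 2] == 0.0
        assert S.values[0, 3] == 0.0  # vs empty set
        assert S.values[3, 3] == 0.0  # empty set carries no evidence
        _assert_valid_similarity(S)


class TestCosine:
    def test_hand_example(self):
        M = AssociationMatrix(
            np.array([[1.0, 0, 1], [1, 0, 0]]), ["d1", "d2"], ["l1", "l2", "l3"]
        )
        S = cosine_profile_similarity(M, "diseases")
        assert S.values[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_identity_orthogonal_and_zero_profile(self):
        M = AssociationMatrix(
            np.array([[1.0, 0], [0, 1], [1, 0], [0, 0]]),
            ["a", "b", "c", "z"],
            ["l1", "l2"],
        )
        S = cosine_profile_similarity(M, "diseases")
        assert S.values[0, 2] == 1.0  # identical nonzero profiles
        assert S.values[0, 1] == 0.0  # orthogonal
        assert S.values[3, 3] == 0.0  # all-zero profile: degenerate diagonal
        assert np.all(S.values[3] == 0.0)

    def test_lncrna_axis_uses_columns(self):
        M = AssociationMatrix(np.array([[1.0, 1], [0, 1]]), ["d1", "d2"], ["l1", "l2"])
        S = cosine_profile_similarity(M, "lncrnas")
        assert S.values[0, 1] == pytest.approx(1 / np.sqrt(2))


class TestSequence:
    def test_identical_sequences_give_one(self):
        ss = SequenceSet({"a": "ACGTACGT", "b": "ACGTACGT"})
        S = sequence_similarity(ss)
        assert S.values[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(S.values) == 1.0)

    def test_negative_raw_score_clamped_to_zero(self):
        ss = SequenceSet({"a": "AAAA", "b": "TTTT"})  # raw cross score -16
        S = sequence_similarity(ss)
        assert S.values[0, 1] == 0.0

    def test_matrix_matches_bruteforce_dp_oracle(self):
        rng = np.random.default_rng(3)
        seqs = {
            f"l{i}": "".join(rng.choice(list("ACGT"), size=50)) for i in range(3)
        }
        S = sequence_similarity(SequenceSet(seqs)).values
        ids = list(seqs)
        for i in range(3):
            for j in range(3):
                raw = max(gotoh_score(seqs[ids[i]], seqs[ids[j]]), 0.0)
                expected = raw / np.sqrt(
                    gotoh_score(seqs[ids[i]], seqs[ids[i]])
                    * gotoh_score(seqs[ids[j]], seqs[ids[j]])
                )
                assert S[i, j] == pytest.approx(expected)


class TestExpression:
    def test_monotone_transform_and_reversal_give_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        E = ExpressionMatrix(
            np.vstack([base, 2 * base + 3, -base]),
            ["l1", "l2", "l3"],
            [f"s{i}" for i in range(5)],
        )
        S = expression_similarity(E)
        assert S.values[0, 1] == pytest.approx(1.0)  # rank invariance
        assert S.values[0, 2] == pytest.approx(1.0)  # |rho| of reversal

    def test_constant_row_isolated(self):
        E = ExpressionMatrix(
            np.array([[1.0, 2, 3], [4, 4, 4]]), ["l1", "l2"], ["s1", "s2", "s3"]
        )
        S = expression_similarity(E)
        assert S.values[0, 1] == 0.0
        assert S.values[1, 1] == 1.0

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 5, size=(4, 10)).astype(float)  # ties likely
        E = ExpressionMatrix(vals, [f"l{i}" for i in range(4)], [f"s{i}" for i in range(10)])
        S = expression_similarity(E).values
        for i in range(4):
            for j in range(i + 1, 4):
                assert S[i, j] == pytest.approx(spearman_abs(vals[i], vals[j]))


class TestSemantic:
    EDGES = [("c", "p"), ("p", "root"), ("q", "root"), ("iso2", "iso")]

    def test_same_single_node_gives_one(self):
        dag = OntologyDag(self.EDGES, decay=0.5)
        S = semantic_similarity_dag(dag, {"d1": {"c"}, "d2": {"c"}}, ["d1", "d2"])
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_child_parent_chain_matches_enumeration_oracle(self):
        edges = [("c", "p")]
        dag = OntologyDag(edges, decay=0.5)
        S = semantic_similarity_dag(dag, {"d1": {"c"}, "d2": {"p"}}, ["d1", "d2"])
        expected = semantic_similarity_enumeration(edges, 0.5, {"c"}, {"p"})
        assert S.values[0, 1] == pytest.approx(expected)
        assert S.values[0, 1] == pytest.approx(0.6)  # (0.5 + 1) / (1.5 + 1)

    def test_multi_node_profiles_match_enumeration_oracle(self):
        dag = OntologyDag(self.EDGES, decay=0.5)
        ti, tj = {"c", "q"}, {"p"}
        S = semantic_similarity_dag(dag, {"d1": ti, "d2": tj}, ["d1", "d2"])
        assert S.values[0, 1] == pytest.approx(
            semantic_similarity_enumeration(self.EDGES, 0.5, ti, tj)
        )

    def test_disjoint_components_give_zero(self):
        dag = OntologyDag(self.EDGES, decay=0.5)
        S = semantic_similarity_dag(dag, {"d1": {"c"}, "d2": {"iso2"}}, ["d1", "d2"])
        assert S.values[0, 1] == 0.0

    def test_unmapped_disease_rejected(self):
        dag = OntologyDag(self.EDGES)
        with pytest.raises(ValueError, match="no DAG node"):
            semantic_similarity_dag(dag, {"d1": {"c"}, "d2": set()}, ["d1", "d2"])


class TestFunctional:
    def _ds(self, values, ids):
        return SimilarityMatrix(np.asarray(values, dtype=float), ids, "semantic")

    def test_identical_disease_sets_give_one(self):
        DS = self._ds([[1, 0.2], [0.2, 1]], ["d1", "d2"])
        assoc = AssociationMatrix(np.array([[1.0, 1], [1, 1]]), ["d1", "d2"], ["l1", "l2"])
        S = lncrna_functional_similarity(DS, assoc)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        DS = self._ds([[1, 0.6], [0.6, 1]], ["d1", "d2"])
        assoc = AssociationMatrix(np.array([[1.0, 0], [0, 1]]), ["d1", "d2"], ["l1", "l2"])
        S = lncrna_functional_similarity(DS, assoc)
        assert S.values[0, 1] == pytest.approx(0.6)  # (0.6 + 0.6) / 2

    def test_orphan_lncrna_isolated(self):
        DS = self._ds([[1, 0.6], [0.6, 1]], ["d1", "d2"])
        assoc = AssociationMatrix(np.array([[1.0, 0], [0, 0]]), ["d1", "d2"], ["l1", "l2"])
        S = lncrna_functional_similarity(DS, assoc)
        assert S.values[0, 1] == 0.0
        assert S.values[1, 1] == 1.0

    def test_random_instance_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        m, n = 5, 5
        raw = rng.random((m, m))
        DSv = (raw + raw.T) / 2
        np.fill_diagonal(DSv, 1.0)
        DS = self._ds(DSv, [f"d{i}" for i in range(m)])
        av = (rng.random((m, n)) < 0.5).astype(float)
        av[0, :] = 1.0  # no empty disease set for any lncRNA
        assoc = AssociationMatrix(av, DS.ids, [f"l{j}" for j in range(n)])
        S = lncrna_functional_similarity(DS, assoc)
        np.testing.assert_allclose(
            S.values, functional_similarity_bruteforce(DSv, av), atol=1e-12
        )


class TestIntegrate:
    S1 = SimilarityMatrix(np.array([[1, 0.2], [0.2, 1.0]]), ["a", "b"])
    S2 = SimilarityMatrix(np.array([[1, 0.6], [0.6, 1.0]]), ["a", "b"])

    @pytest.mark.parametrize("w, expected", [(1.0, 0.2), (0.0, 0.6), (0.5, 0.4)])
    def test_convex_combination(self, w, expected):
        assert integrate(self.S1, self.S2, w).values[0, 1] == pytest.approx(expected)

    @given(w=st.floats(0, 1))
    def test_linearity(self, w):
        lhs = integrate(self.S1, self.S2, w).values + integrate(self.S2, self.S1, w).values
        np.testing.assert_allclose(lhs, self.S1.values + self.S2.values, atol=1e-12)

    def test_label_mismatch_rejected(self):
        other = SimilarityMatrix(np.eye(2), ["a", "c"])
        with pytest.raises(ValueError):
            integrate(self.S1, other, 0.5)


class TestWeightTuning:
    def test_constant_auc_ties_break_toward_larger_weight(self):
        w, table = tune_weight_grid(lambda wd, wl: 0.7)
        assert (w.w_d, w.w_l) == (1.0, 1.0)
        assert len(table) == 100

    def test_planted_optimum_recovered(self):
        w, _ = tune_weight_grid(lambda wd, wl: -((wd - 0.7) ** 2) - (wl - 0.5) ** 2)
        assert (w.w_d, w.w_l) == (0.7, 0.5)

    def test_callback_failure_reported_with_grid_context(self):
        def bad(wd, wl):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="w_d=0.1"):
            tune_weight_grid(bad)


@given(
    hnp.arrays(
        np.float64,
        (4, 6),
        elements=st.sampled_from([0.0, 1.0]),
    )
)
def test_cosine_similarity_always_valid(values):
    M = AssociationMatrix(values, [f"d{i}" for i in range(4)], [f"l{j}" for j in range(6)])
    for axis in ("diseases", "lncrnas"):
        _assert_valid_similarity(cosine_profile_similarity(M, axis))
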