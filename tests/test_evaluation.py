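import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetmc import (
    AssociationMatrix,
    RankedPredictions,
    global_loocv,
    kfold_cv,
    local_loocv,
    matrix_sparsity,
    permutation_contribution,
    precision_recall_at_ranks,
    roc_pr_from_scores,
)
from hetmc.evaluation import make_folds, truncate_significant
from oracles import auc_pair_counting


class TestRocPr:
    def test_perfect_separation(self):
        assert roc_pr_from_scores([0.9, 0.8], [0.2, 0.1]).auc == 1.0

    def test_identical_distributions_give_half(self):
        res = roc_pr_from_scores([0.3, 0.7], [0.3, 0.7])
        assert res.auc == 0.5

    def test_hand_counted_case(self):
        # pairs: (0.9 beats both), (0.4 beats 0.1 only) -> 3/4
        assert roc_pr_from_scores([0.9, 0.4], [0.6, 0.1]).auc == 0.75

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_from_scores([], [0.5])

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 2**16))
    def test_matches_pair_counting_oracle(self, npos, nneg, bits):
        rng = np.random.default_rng(bits)
        pos = np.round(rng.random(npos), 2)  # rounding forces ties
        neg = np.round(rng.random(nneg), 2)
        assert roc_pr_from_scores(pos, neg).auc == pytest.approx(
            auc_pair_counting(pos, neg)
        )


def _score_equals_truth(assoc: AssociationMatrix):
    """Model that scores with the full (pre-removal) association matrix."""
    full = assoc.values.copy()
    return lambda train: full


class TestLoocv:
    def test_truth_scoring_model_is_perfect_globally(self, synth_small):
        res = global_loocv(synth_small.observed, _score_equals_truth(synth_small.observed))
        assert res.auc == 1.0

    def test_truth_scoring_model_is_perfect_locally(self, synth_small):
        res = local_loocv(synth_small.observed, _score_equals_truth(synth_small.observed))
        assert res.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        vals = (rng.random((20, 15)) < 0.7).astype(float)  # 200+ known pairs
        assoc = AssociationMatrix(vals, [f"d{i}" for i in range(20)], [f"l{j}" for j in range(15)])
        rng2 = np.random.default_rng(1)
        res = global_loocv(assoc, lambda train: rng2.random(train.shape))
        assert abs(res.auc - 0.5) <= 0.08

    def test_each_fold_removes_exactly_one_pair(self, synth_small):
        seen = []

        def spy(train):
            seen.append(int(train.sum()))
            return np.zeros_like(train)

        n_known = synth_small.observed.n_known
        global_loocv(synth_small.observed, spy)
        assert seen == [n_known - 1] * n_known

    def test_local_candidates_restricted_to_one_disease(self):
        vals = np.array([[1.0, 0], [0, 1], [0, 0]])
        assoc = AssociationMatrix(vals, ["d1", "d2", "d3"], ["l1", "l2"])
        # high-scoring unknown pairs of a disease with no held-out fold must
        # hurt the global protocol but be invisible to the local one
        S = np.array([[0.9, 0.1], [0.1, 0.9], [0.95, 0.95]])
        assert local_loocv(assoc, lambda train: S).auc == 1.0
        assert global_loocv(assoc, lambda train: S).auc < 1.0


class TestKfold:
    def test_fold_partition_properties(self):
        rng = np.random.default_rng(0)
        folds = make_folds(10, 5, rng)
        assert [len(f) for f in folds] == [2] * 5
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))

    def test_remainder_spread_one_per_fold(self):
        rng = np.random.default_rng(0)
        sizes = sorted(len(f) for f in make_folds(13, 5, rng))
        assert sizes == [2, 2, 3, 3, 3]

    def test_same_seed_same_folds(self):
        f1 = make_folds(17, 5, np.random.default_rng(4))
        f2 = make_folds(17, 5, np.random.default_rng(4))
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_k_equals_n_known_reduces_to_loocv(self, synth_small):
        model = _score_equals_truth(synth_small.observed)
        n = synth_small.observed.n_known
        res_k = kfold_cv(synth_small.observed, model, k=n, seed=0)
        res_l = global_loocv(synth_small.observed, model)
        assert res_k.auc == res_l.auc == 1.0

    def test_heldout_fold_absent_from_training(self, synth_small):
        n_known = synth_small.observed.n_known

        def spy(train):
            # every fold must remove its whole test set from training
            assert int(train.sum()) in (n_known - n_known // 5, n_known - (n_known // 5 + 1))
            return np.zeros_like(train)

        kfold_cv(synth_small.observed, spy, k=5, seed=0)

    def test_repeats_report_spread(self, synth_small):
        rng = np.random.default_rng(2)
        res = kfold_cv(
            synth_small.observed, lambda t: rng.random(t.shape), k=5, repeats=3, seed=1
        )
        assert len(res.extra["auc_per_repeat"]) == 3
        assert res.extra["auc_sd"] >= 0.0


class TestPrecisionRecallAtRanks:
    def _preds(self, scores, flags):
        entries = [(f"d{i}", "l0", s, f) for i, (s, f) in enumerate(zip(scores, flags))]
        entries.sort(key=lambda e: -e[2])
        return RankedPredictions(entries, list(range(1, len(entries) + 1)),
                                 list(range(1, len(entries) + 1)))

    def test_toy_list(self):
        # 6 pairs, positives at ranks 1 and 4
        preds = self._preds([0.9, 0.8, 0.7, 0.6, 0.5, 0.4],
                            [True, False, False, True, False, False])
        prec, rec = precision_recall_at_ranks(preds, cutoffs=[4])
        assert prec[4] == 0.5 and rec[4] == 1.0

    def test_all_positives_in_top_k(self):
        preds = self._preds([0.9, 0.8, 0.1], [True, True, False])
        prec, rec = precision_recall_at_ranks(preds, cutoffs=[2])
        assert prec[2] == 1.0 and rec[2] == 1.0

    def test_no_positives_in_top_k(self):
        preds = self._preds([0.9, 0.8, 0.1], [False, False, True])
        prec, rec = precision_recall_at_ranks(preds, cutoffs=[2])
        assert prec[2] == 0.0 and rec[2] == 0.0


class TestPermutation:
    def test_similarity_permutation_preserves_structure(self):
        rng = np.random.default_rng(0)
        S = rng.random((6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        calls = []

        def ev(ds, ls, dl):
            calls.append(ds)
            return 0.5

        permutation_contribution(S, np.eye(3), np.zeros((6, 3)), "DS", ev, n_reps=3, seed=1)
        for ds in calls:
            np.testing.assert_array_equal(ds, ds.T)
            np.testing.assert_array_equal(np.diag(ds), 1.0)
            assert np.allclose(np.sort(ds.ravel()), np.sort(S.ravel()))

    def test_association_shuffle_preserves_count(self):
        dl = np.zeros((5, 4))
        dl[[0, 1, 2], [0, 1, 2]] = 1.0
        seen = []
        permutation_contribution(
            np.eye(5), np.eye(4), dl, "DL", lambda d, l, a: seen.append(a.sum()) or 0.5,
            n_reps=4, seed=2,
        )
        assert seen == [3.0] * 4

    def test_fixed_seed_reproducible(self):
        dl = np.eye(4)
        r1 = permutation_contribution(np.eye(4), np.eye(4), dl, "DL",
                                      lambda d, l, a: float(a[0, 0]), n_reps=5, seed=3)
        r2 = permutation_contribution(np.eye(4), np.eye(4), dl, "DL",
                                      lambda d, l, a: float(a[0, 0]), n_reps=5, seed=3)
        assert r1["auc_values"] == r2["auc_values"]


class TestSparsity:
    @pytest.mark.parametrize(
        "nnz, m, n, expected",
        [
            (352, 190, 156, 1.187e-2),
            (540, 178, 115, 2.638e-2),
            (621, 226, 258, 1.065e-2),
        ],
    )
    def test_catalogue_scale_densities(self, nnz, m, n, expected):
        rng = np.random.default_rng(0)
        vals = np.zeros((m, n))
        vals.flat[rng.choice(m * n, size=nnz, replace=False)] = 1.0
        assoc = AssociationMatrix(vals, [f"d{i}" for i in range(m)], [f"l{j}" for j in range(n)])
        assert matrix_sparsity(assoc) == pytest.approx(expected, rel=1e-9)

    def test_boundaries(self):
        empty = AssociationMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "y"])
        full = AssociationMatrix(np.ones((2, 2)), ["a", "b"], ["x", "y"])
        assert matrix_sparsity(empty) == 0.0
        assert matrix_sparsity(full) == 1.0

    def test_truncation_not_rounding(self):
        assert truncate_significant(0.0118758, 4) == pytest.approx(0.01187)
        assert truncate_significant(0.9999999, 4) == pytest.approx(0.9999)
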