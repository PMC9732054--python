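import numpy as np
import pandas as pd
import pytest

import lulcst as L
from lulcst.errors import ArgumentError

HAND_MATRIX = L.ErrorMatrix(counts=[[40, 10], [5, 45]])


class TestBuildErrorMatrix:
    def test_perfect_agreement_is_diagonal(self):
        labels = np.array([[0, 1], [2, 0]])
        lm = L.LabelMap(labels=labels, class_names=["a", "b", "c"])
        ref = pd.DataFrame({"row": [0, 0, 1, 1], "col": [0, 1, 0, 1],
                            "label": [0, 1, 2, 0]})
        em = L.build_error_matrix(lm, ref)
        assert np.array_equal(em.counts, np.diag([2, 1, 1]))

    def test_single_disagreement_lands_at_predicted_reference_cell(self):
        lm = L.LabelMap(labels=np.full((1, 1), 2), class_names=list("abcdef"))
        ref = pd.DataFrame({"row": [0], "col": [0], "label": [5]})
        em = L.build_error_matrix(lm, ref)
        assert em.counts[2, 5] == 1 and em.counts.sum() == 1

    def test_matches_hand_tally_on_synthetic_confusions(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 6, size=(40, 40))
        lm = L.LabelMap(labels=pred, class_names=list("abcdef"))
        rows = rng.integers(0, 40, 240)
        cols = rng.integers(0, 40, 240)
        refs = rng.integers(0, 6, 240)
        em = L.build_error_matrix(lm, pd.DataFrame(
            {"row": rows, "col": cols, "label": refs}))
        tally = np.zeros((6, 6), dtype=int)
        for r, c, k in zip(rows, cols, refs):
            tally[pred[r, c], k] += 1
        assert np.array_equal(em.counts, tally)

    def test_empty_reference_rejected(self):
        lm = L.LabelMap(labels=np.zeros((2, 2), dtype=int))
        with pytest.raises(ArgumentError):
            L.build_error_matrix(lm, pd.DataFrame(
                columns=["row", "col", "label"]))


class TestAccuracyStatistics:
    def test_diagonal_matrix_is_perfect(self):
        em = L.ErrorMatrix(counts=np.diag([7, 3, 5]))
        assert (L.producers_accuracy(em) == 100.0).all()
        assert (L.users_accuracy(em) == 100.0).all()
        assert L.overall_accuracy(em) == 100.0
        assert L.kappa(em) == pytest.approx(1.0)

    def test_hand_arithmetic_two_class_matrix(self):
        em = HAND_MATRIX
        assert L.producers_accuracy(em)[0] == pytest.approx(100 * 40 / 45)
        assert L.users_accuracy(em)[0] == pytest.approx(80.0)
        assert L.overall_accuracy(em) == pytest.approx(85.0)
        # po = 0.85, pe = (50*45 + 50*55)/100^2 = 0.5
        assert L.kappa(em) == pytest.approx(0.70, abs=1e-12)

    def test_all_off_diagonal_is_zero_accuracy(self):
        em = L.ErrorMatrix(counts=[[0, 3], [4, 0]])
        assert L.overall_accuracy(em) == 0.0

    def test_chance_level_matrix_has_zero_kappa(self):
        # counts proportional to the product of marginals
        em = L.ErrorMatrix(counts=np.outer([10, 30], [20, 20]))
        assert L.kappa(em) == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_column_reported_missing(self):
        em = L.ErrorMatrix(counts=[[5, 1, 0], [0, 4, 0], [0, 0, 0]])
        assert np.isnan(L.producers_accuracy(em)[2])
        assert np.isnan(L.users_accuracy(em)[2])


class TestInvariants:
    def test_overall_is_count_weighted_mean_of_users_accuracy(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=(5, 5))
        counts[np.diag_indices(5)] += 5
        em = L.ErrorMatrix(counts=counts)
        rows = counts.sum(axis=1)
        weighted = np.nansum(L.users_accuracy(em) * rows) / rows.sum()
        assert L.overall_accuracy(em) == pytest.approx(weighted)

    def test_class_permutation_leaves_overall_and_kappa_unchanged(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 20, size=(4, 4)) + np.diag([9, 9, 9, 9])
        perm = rng.permutation(4)
        em = L.ErrorMatrix(counts=counts)
        emp = L.ErrorMatrix(counts=counts[np.ix_(perm, perm)])
        assert L.overall_accuracy(emp) == pytest.approx(
            L.overall_accuracy(em))
        assert L.kappa(emp) == pytest.approx(L.kappa(em))
        assert np.allclose(L.producers_accuracy(emp),
                           L.producers_accuracy(em)[perm], equal_nan=True)

    def test_kappa_is_one_iff_diagonal(self):
        assert L.kappa(L.ErrorMatrix(counts=np.diag([3, 9]))) == \
            pytest.approx(1.0)
        assert L.kappa(HAND_MATRIX) < 1.0


def test_accuracy_table_schema():
    df = L.accuracy_table(HAND_MATRIX)
    assert list(df.columns) == ["class", "producers_accuracy_pct",
                                "users_accuracy_pct",
                                "overall_accuracy_pct", "kappa"]
    assert len(df) == 2
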