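import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventdose import (
    cv_percent_error,
    enumerate_subsets,
    fit_lmm,
    grouped_kfold,
    predict,
    select_best,
)
from conftest import build_table, toy_lmm_dataset
from ventdose.synthetic import TruthParams


class TestEnumerateSubsets:
    def test_three_names_hand_enumeration(self):
        got = enumerate_subsets(["a", "b", "c"])
        assert got == [
            ("a",), ("b",), ("c",),
            ("a", "b"), ("a", "c"), ("b", "c"),
            ("a", "b", "c"),
        ]

    def test_single_name(self):
        assert enumerate_subsets(["hr"]) == [("hr",)]

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=1, max_value=10))
    def test_count_and_uniqueness(self, p):
        names = [f"v{i}" for i in range(p)]
        subsets = enumerate_subsets(names)
        assert len(subsets) == 2**p - 1
        assert len(set(subsets)) == len(subsets)
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subsets([])


class TestGroupedKFold:
    def test_fifteen_subjects_five_folds_of_three(self):
        fold_map = grouped_kfold([f"s{i}" for i in range(15)], 5, seed=0)
        sizes = pd.Series(fold_map).value_counts()
        assert (sizes == 3).all() and len(sizes) == 5

    def test_balanced_remainder(self):
        fold_map = grouped_kfold([f"s{i}" for i in range(7)], 5, seed=1)
        sizes = sorted(pd.Series(fold_map).value_counts().tolist())
        assert sizes == [1, 1, 1, 2, 2]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=6))
    def test_partition_property(self, seed, k):
        ids = [f"s{i}" for i in range(12)]
        fold_map = grouped_kfold(ids, k, seed)
        assert set(fold_map) == set(ids)
        for fold in range(k):
            val = {s for s, f in fold_map.items() if f == fold}
            train = {s for s, f in fold_map.items() if f != fold}
            assert not val & train
            assert val | train == set(ids)

    def test_deterministic_in_seed(self):
        ids = [f"s{i}" for i in range(9)]
        assert grouped_kfold(ids, 3, 7) == grouped_kfold(ids, 3, 7)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(["a", "b"], 3, 0)
        with pytest.raises(ValueError):
            grouped_kfold(["a", "b", "c"], 1, 0)


class TestCrossValidation:
    def test_perfect_model_has_zero_percent_error(self, noiseless_study):
        cv = cv_percent_error(noiseless_study["table"], ["hr", "fb"], k=2, seed=0)
        assert abs(cv.mean_pe) < 1e-6
        assert cv.sd_pe < 1e-6

    def test_matches_hand_rolled_fold_loop(self):
        """Independent loop oracle: refit and predict per fold by hand."""
        df = toy_lmm_dataset(21, n_subjects=4, n_per=6, beta=(5.0, 0.4), tau=0.2, sigma=0.3)
        df["y"] += 3.0  # keep observations positive
        cv = cv_percent_error(df, ["x"], k=2, seed=3, response="y")
        fold_map = cv.fold_map
        pooled = []
        for fold in range(2):
            val = [s for s, f in fold_map.items() if f == fold]
            train_df = df[~df["subject_id"].isin(val)]
            fit = fit_lmm(train_df, ["x"], response="y")
            val_df = df[df["subject_id"].isin(val)]
            pred = predict(fit, val_df)
            pooled.append(100.0 * (pred - val_df["y"].to_numpy()) / val_df["y"].to_numpy())
        pooled = np.concatenate(pooled)
        assert np.sort(cv.percent_errors) == pytest.approx(np.sort(pooled), abs=1e-9)
        assert cv.mean_pe == pytest.approx(pooled.mean(), abs=1e-9)

    def test_summary_recomputable_from_pooled_errors(self, study):
        cv = cv_percent_error(study["table"], ["hr", "fb"], k=5, seed=2)
        assert cv.mean_pe == pytest.approx(cv.percent_errors.mean(), abs=1e-9)
        assert cv.sd_pe == pytest.approx(cv.percent_errors.std(ddof=1), abs=1e-9)

    def test_row_order_invariance(self, study):
        table = study["table"]
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = cv_percent_error(table, ["hr", "fb"], k=5, seed=9)
        b = cv_percent_error(shuffled, ["hr", "fb"], k=5, seed=9)
        # identical up to float summation-order noise in the profiled REML
        assert a.mean_pe == pytest.approx(b.mean_pe, abs=1e-6)
        assert a.fold_map == b.fold_map

    def test_nonpositive_validation_response_rejected(self):
        df = toy_lmm_dataset(22, n_subjects=4, n_per=6)
        df.loc[0, "y"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            cv_percent_error(df, ["x"], k=2, seed=0, response="y")

    def test_folds_never_leak_subjects(self, study):
        """Train and validation subject sets are disjoint on every fold."""
        table = study["table"]
        for seed in range(10):
            cv = cv_percent_error(table, ["hr"], k=5, seed=seed)
            folds = pd.Series(cv.fold_map)
            assert set(folds.index) == set(table["subject_id"].unique())
            for fold in folds.unique():
                val = set(folds[folds == fold].index)
                train = set(folds[folds != fold].index)
                assert not val & train


class TestSelectBest:
    def make_table(self, rows):
        return pd.DataFrame(rows)

    def test_single_candidate_returned_unconditionally(self):
        table = self.make_table(
            [dict(predictors="hr", size=1, aic=100.0, mean_pe=9.0, sd_pe=30.0,
                  all_significant=False, max_pvalue=0.3)]
        )
        row, report = select_best(table, 1)
        assert row["predictors"] == "hr"

    def test_double_winner_chosen_outright(self):
        table = self.make_table(
            [
                dict(predictors="hr+fb", size=2, aic=100.0, mean_pe=5.0, sd_pe=20.0,
                     all_significant=True, max_pvalue=0.01),
                dict(predictors="hr+act", size=2, aic=110.0, mean_pe=8.0, sd_pe=25.0,
                     all_significant=True, max_pvalue=0.01),
            ]
        )
        row, report = select_best(table, 2)
        assert row["predictors"] == "hr+fb"
        assert "both" in report["criterion"]

    def test_disagreement_resolved_by_estimate_confidence(self):
        """PE and AIC disagree; the candidate with all coefficients
        significant (smaller worst-case p-value) wins."""
        table = self.make_table(
            [
                dict(predictors="hr+fb", size=2, aic=100.0, mean_pe=6.0, sd_pe=20.0,
                     all_significant=True, max_pvalue=0.001),
                dict(predictors="hr+act", size=2, aic=120.0, mean_pe=5.0, sd_pe=25.0,
                     all_significant=False, max_pvalue=0.4),
            ]
        )
        row, report = select_best(table, 2)
        assert row["predictors"] == "hr+fb"
        assert "p-value" in report["criterion"]

    def test_disagreement_with_equal_confidence_falls_back_to_percent_error(self):
        table = self.make_table(
            [
                dict(predictors="a+b", size=2, aic=100.0, mean_pe=6.0, sd_pe=20.0,
                     all_significant=False, max_pvalue=0.2),
                dict(predictors="a+c", size=2, aic=120.0, mean_pe=-5.0, sd_pe=25.0,
                     all_significant=False, max_pvalue=0.2),
            ]
        )
        row, report = select_best(table, 2)
        assert row["predictors"] == "a+c"
        assert "percent error" in report["criterion"]

    def test_unscoreable_percent_error_defers_to_aic(self):
        """A subset whose CV could not be computed cannot be the PE winner."""
        table = self.make_table(
            [
                dict(predictors="a+b", size=2, aic=100.0, mean_pe=np.nan, sd_pe=np.nan,
                     all_significant=True, max_pvalue=0.01),
                dict(predictors="a+c", size=2, aic=105.0, mean_pe=4.0, sd_pe=20.0,
                     all_significant=True, max_pvalue=0.01),
            ]
        )
        row, _ = select_best(table, 2)
        assert row["predictors"] == "a+c"

    def test_missing_size_rejected(self):
        table = self.make_table(
            [dict(predictors="hr", size=1, aic=1.0, mean_pe=1.0, sd_pe=1.0,
                  all_significant=True, max_pvalue=0.01)]
        )
        with pytest.raises(ValueError):
            select_best(table, 3)
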