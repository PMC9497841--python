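"""Feature matrix, correlation filtering, RF ranking and coarse trees."""

import numpy as np
import pandas as pd
import pytest

from cfaekit.selection import (
    CoarseTreeClassifier,
    CorrelationFilter,
    GiniImportanceRanker,
    averaged_correlation_matrix,
    build_feature_matrix,
    coarse_tree_fit,
    correlation_filter,
    lopo_accuracy,
    single_feature_accuracies,
    subset_search,
)
from cfaekit.synthetic import SITES


def toy_tables(n_par=2, n_per=2, sites=SITES, se_offset=0.0):
    """Minimal per-segment and per-recording tables for matrix assembly."""
    seg_rows, rec_rows = [], []
    rng = np.random.default_rng(0)
    for cls, n, base in (("ParAF", n_par, 0.2), ("PerAF", n_per, 0.6)):
        for i in range(n):
            pid = f"{cls}{i}"
            for site in sites:
                for w in (1, 2, 4):
                    for seg in range(16 // w):
                        seg_rows.append(
                            [pid, cls, site, w, seg + 1, 1, base + se_offset + rng.normal(0, 0.01), 0.5]
                        )
                rec_rows.append([pid, cls, site, 160.0 + rng.normal(0, 5), 6.0 + rng.normal(0, 0.2)])
    seg = pd.DataFrame(
        seg_rows, columns=["patient_id", "af_type", "site", "w", "segment", "quality", "SE", "DET"]
    )
    rec = pd.DataFrame(rec_rows, columns=["patient_id", "af_type", "site", "AFCL_ms", "DF_Hz"])
    return seg, rec


class TestFeatureMatrix:
    def test_shape_and_label_coding(self):
        seg, rec = toy_tables()
        fm = build_feature_matrix(seg, rec, w=1)
        assert fm.shape == (4, 25)  # 24 features + TYPE
        assert list(fm["TYPE"]) == [0, 0, 1, 1]

    def test_discarded_segments_do_not_change_cells(self):
        seg, rec = toy_tables()
        poisoned = seg.copy()
        mask = (poisoned["segment"] == 3) & (poisoned["w"] == 1)
        poisoned.loc[mask, "quality"] = 0
        fm_clean = build_feature_matrix(seg[~mask], rec, w=1)
        poisoned.loc[mask, "SE"] = 1e9  # sentinel: must never be read
        fm_poisoned = build_feature_matrix(poisoned, rec, w=1)
        pd.testing.assert_frame_equal(fm_clean, fm_poisoned)

    def test_missing_site_left_nan(self):
        seg, rec = toy_tables()
        seg = seg[~((seg["patient_id"] == "ParAF0") & (seg["site"] == "POS"))]
        rec = rec[~((rec["patient_id"] == "ParAF0") & (rec["site"] == "POS"))]
        fm = build_feature_matrix(seg, rec, w=1)
        assert np.isnan(fm.loc["ParAF0", "SEPOS"])
        assert not np.isnan(fm.loc["ParAF1", "SEPOS"])


class TestAveragedCorrelation:
    def test_identical_matrices_average_to_single(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        avg = averaged_correlation_matrix([m, m, m])
        single = averaged_correlation_matrix([m])
        pd.testing.assert_frame_equal(avg, single)

    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame({"a": rng.normal(size=10)})
        m["b"] = m["a"]
        avg = averaged_correlation_matrix([m])
        assert avg.loc["a", "b"] == pytest.approx(1.0)

    def test_equals_pairwise_formula_on_fixture(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        avg = averaged_correlation_matrix([m])
        for a in "abcd":
            for b in "abcd":
                x, y = m[a].to_numpy(), m[b].to_numpy()
                r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                )
                assert avg.loc[a, b] == pytest.approx(r, rel=1e-12)

    def test_constant_column_flagged_nan(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        avg = averaged_correlation_matrix([m])
        assert np.isnan(avg.loc["a", "b"])

    def test_mismatched_columns_rejected(self):
        m1 = pd.DataFrame({"a": [1.0, 2.0]})
        m2 = pd.DataFrame({"b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            averaged_correlation_matrix([m1, m2])


class TestCorrelationFilter:
    def test_identical_pair_loses_exactly_one(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=50), "c": rng.normal(size=50)})
        X.insert(1, "b", X["a"])
        kept = CorrelationFilter(cutoff=0.6).fit(X).retained_
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_member_with_higher_mean_correlation_dropped(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=200)
        x3 = rng.normal(size=200)
        # x2 is redundant with x1 AND leans on x3, so its mean |r| is higher
        x2 = x1 + 0.25 * x3 + 0.05 * rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        kept = CorrelationFilter(cutoff=0.6).fit(X).retained_
        assert kept == ["x1", "x3"]

    def test_uncorrelated_features_all_kept(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        assert CorrelationFilter(cutoff=0.6).fit(X).retained_ == list("abcde")

    def test_invariant_to_row_order_and_positive_scaling(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        X["b"] = X["a"] * 0.9 + 0.1 * rng.normal(size=60)
        base = CorrelationFilter(cutoff=0.6).fit(X).retained_
        shuffled = X.sample(frac=1.0, random_state=1)
        scaled = X * [3.0, 0.5, 10.0, 1.0]
        assert CorrelationFilter(cutoff=0.6).fit(shuffled).retained_ == base
        assert CorrelationFilter(cutoff=0.6).fit(scaled).retained_ == base


class TestGiniRanking:
    @staticmethod
    def planted(seed, n=60, noise_features=9):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        informative = y + 0.05 * rng.normal(size=n)
        X = pd.DataFrame(
            {"signal": informative}
            | {f"noise{i}": rng.normal(size=n) for i in range(noise_features)}
        )
        return X, y

    def test_planted_feature_scores_100_noise_below_40(self):
        wins = 0
        for seed in range(25):
            X, y = self.planted(seed)
            ranker = GiniImportanceRanker(n_trees=500, random_state=seed).fit(X, y)
            scores = dict(zip(ranker.feature_names_in_, ranker.scores_))
            if scores["signal"] == 100.0 and all(
                v < 40.0 for k, v in scores.items() if k != "signal"
            ):
                wins += 1
        assert wins >= 24  # >= 95% of 25 seeds

    def test_max_score_is_100_by_construction(self):
        X, y = self.planted(0)
        ranker = GiniImportanceRanker(random_state=0).fit(X, y)
        assert ranker.scores_.max() == pytest.approx(100.0)

    def test_label_permutation_destroys_lead(self):
        X, y = self.planted(0)
        lead = []
        for labels in (y, np.random.default_rng(0).permutation(y)):
            ranker = GiniImportanceRanker(n_trees=200, random_state=0).fit(X, labels)
            scores = dict(zip(ranker.feature_names_in_, ranker.scores_))
            noise_max = max(v for k, v in scores.items() if k != "signal")
            lead.append(scores["signal"] - noise_max)
        assert lead[1] < lead[0] - 30.0

    def test_single_class_rejected(self):
        X, _ = self.planted(0)
        with pytest.raises(ValueError):
            GiniImportanceRanker().fit(X, np.zeros(len(X)))


class TestCoarseTree:
    def test_separable_single_feature_single_split(self):
        X = np.array([[0.1], [0.2], [0.3], [0.8], [0.9], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        tree = coarse_tree_fit(pd.DataFrame(X), y)
        assert tree.n_splits_ == 1
        assert (tree.predict(X) == y).all()

    def test_constant_feature_gives_majority_stump(self):
        X = np.ones((7, 1))
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        tree = coarse_tree_fit(pd.DataFrame(X), y)
        assert tree.n_splits_ == 0
        assert (tree.predict(X) == 0).all()

    def test_split_cap_respected_on_hard_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 3))
        y = rng.integers(0, 2, 200)
        tree = coarse_tree_fit(pd.DataFrame(X), y)
        assert tree.n_splits_ <= 4

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            coarse_tree_fit(pd.DataFrame(index=[0, 1]), [0, 1])


class TestLopo:
    @staticmethod
    def cohort(n=10, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        x = y * 1.0 + 0.05 * rng.normal(size=n) if informative else rng.normal(size=n)
        X = pd.DataFrame({"f": x, "g": rng.normal(size=n)})
        pids = np.array([f"p{i}" for i in range(n)])
        return X, y, pids

    def test_separable_cohort_perfect_accuracy(self):
        X, y, pids = self.cohort()
        assert lopo_accuracy(X, y, pids) == 100.0

    def test_null_cohort_near_majority_rate(self):
        accs = [
            lopo_accuracy(*self.cohort(n=30, informative=False, seed=s)) for s in range(10)
        ]
        assert abs(np.mean(accs) - 50.0) <= 10.0

    def test_equals_bruteforce_fold_loop(self):
        X, y, pids = self.cohort(n=6, seed=3)
        acc, preds = lopo_accuracy(X, y, pids, return_predictions=True)
        correct = 0
        for pid in pids:
            test = pids == pid
            tree = CoarseTreeClassifier(random_state=0).fit(X[~test], y[~test])
            correct += int((tree.predict(X[test]) == y[test]).sum())
        assert acc == pytest.approx(100.0 * correct / len(y))
        assert len(preds) == len(y)

    def test_fold_count_equals_patient_count(self):
        X, y, pids = self.cohort(n=8)
        _, preds = lopo_accuracy(X, y, pids, return_predictions=True)
        assert preds["patient_id"].nunique() == 8

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            lopo_accuracy(pd.DataFrame({"f": [1.0, 2.0]}), [0, 1], ["a", "b"])


class TestSubsetSearch:
    def test_all_nonempty_subsets_evaluated(self):
        X, y, pids = TestLopo.cohort(n=8)
        X = pd.concat([X] * 3, axis=1)
        X.columns = [f"c{i}" for i in range(6)]
        X = X.iloc[:, :5]
        _, table = subset_search(X, y, pids)
        assert len(table) == 2**5 - 1

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(9)
        n = 24
        y = np.tile([0, 1], n // 2)
        # complementary informative pair: each feature carries the class
        # signal for half the patients and is silent for the other half
        half = np.arange(n) < n // 2
        a = np.where(half, 2.0 * y - 1.0, 0.0) + 0.05 * rng.normal(size=n)
        b = np.where(~half, 2.0 * y - 1.0, 0.0) + 0.05 * rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "n1": rng.normal(size=n), "n2": rng.normal(size=n)})
        best, _ = subset_search(X, y, [f"p{i}" for i in range(n)])
        assert set(best.features) >= {"a", "b"}

    def test_tie_broken_toward_smaller_subset(self):
        X, y, pids = TestLopo.cohort(n=10)
        X = X.copy()
        X["f_dup"] = X["f"]  # adding the duplicate cannot change accuracy
        best, _ = subset_search(X[["f", "f_dup"]], y, pids)
        assert best.features == ("f",)

    def test_combinatorial_guard(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 13)))
        X.columns = [f"c{i}" for i in range(13)]
        with pytest.raises(ValueError):
            subset_search(X, np.repeat([0, 1], 5), [f"p{i}" for i in range(10)])


class TestSingleFeature:
    def test_planted_feature_tops_table(self):
        X, y, pids = TestLopo.cohort(n=12)
        table = single_feature_accuracies(X, y, pids)
        assert table.iloc[0]["feature"] == "f"
        assert len(table) == X.shape[1]

    def test_one_row_per_feature(self):
        X, y, pids = TestLopo.cohort(n=8)
        X["h"] = 0.5
        table = single_feature_accuracies(X, y, pids)
        assert sorted(table["feature"]) == sorted(X.columns)
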