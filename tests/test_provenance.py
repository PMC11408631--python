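import warnings

import numpy as np
import pandas as pd
import pytest

from otoprov import provenance
from otoprov.provenance import (
    EmptyReferenceError,
    ThresholdRule,
    assign_by_threshold,
    classify_unlabeled,
    compute_threshold,
    compute_thresholds,
    fit_lda,
    loocv,
    proportions_by_group,
)


def make_table(rows):
    """rows: (fish_id, region, age, year_class, juvenile_d18O, larval_d18O, larval_d13C, radius)"""
    df = pd.DataFrame(
        rows,
        columns=[
            "fish_id", "region", "age", "year_class", "juvenile_d18O",
            "larval_d18O", "larval_d13C", "radius_at_60dph_um",
        ],
    )
    df["capture_date"] = pd.Timestamp("2015-09-01")
    df["has_increment_reading"] = True
    df["label"] = "unclassified"
    return df


class TestThreshold:
    def test_threshold_is_reference_maximum(self):
        rows = [
            (f"F{i}", "WestKyushu", 0, 2015, juv, -0.7, -8.0, 300.0)
            for i, juv in enumerate([-1.5, -0.9, -1.7, -1.2])
        ]
        rule = compute_threshold(make_table(rows), 2015)
        assert rule.threshold_permil == pytest.approx(-0.9)
        assert rule.n_reference == 4

    def test_pacific_offshore_never_in_reference(self):
        rows = [
            ("A", "WestKyushu", 0, 2015, -1.5, -0.7, -8.0, 300.0),
            ("B", "PacificOffshore", 0, 2015, 0.5, -0.1, -8.0, 320.0),
        ]
        rule = compute_threshold(make_table(rows), 2015)
        assert rule.threshold_permil == pytest.approx(-1.5)
        assert rule.n_reference == 1

    def test_age1_west_kyushu_counts_as_reference_but_age1_oki_does_not(self):
        rows = [
            ("A", "WestKyushu", 1, 2015, -1.0, -0.7, -8.0, 300.0),
            ("B", "OkiIslands", 1, 2015, -0.1, -0.3, -8.0, 340.0),
        ]
        rule = compute_threshold(make_table(rows), 2015)
        assert rule.threshold_permil == pytest.approx(-1.0)

    def test_empty_reference_names_year_class(self):
        rows = [("A", "OkiIslands", 1, 2015, -1.0, -0.7, -8.0, 300.0)]
        with pytest.raises(EmptyReferenceError, match="2015"):
            compute_threshold(make_table(rows), 2015)

    def test_threshold_monotone_in_reference_superset(self, stage_table):
        base = stage_table[stage_table["year_class"] == 2015]
        ref = base[provenance._reference_mask(base)]
        rule_all = compute_threshold(base, 2015)
        sub = base.drop(index=ref.index[: len(ref) // 2])
        rule_sub = compute_threshold(sub, 2015)
        assert rule_all.threshold_permil >= rule_sub.threshold_permil


class TestAssignByThreshold:
    RULES = {2015: ThresholdRule(2015, -0.9, 4)}

    def test_boundary_tie_is_local_and_strict_above_is_nonlocal(self):
        rows = [
            ("A", "OkiIslands", 1, 2015, -0.9, -0.7, -8.0, 300.0),
            ("B", "OkiIslands", 1, 2015, -0.89, -0.3, -8.0, 340.0),
        ]
        out = assign_by_threshold(make_table(rows), self.RULES)
        assert out.set_index("fish_id")["label"].to_dict() == {"A": "local", "B": "nonlocal"}

    def test_age0_without_juvenile_is_local_age1_stays_unclassified(self):
        rows = [
            ("A", "OkiIslands", 0, 2015, np.nan, -0.7, -8.0, 300.0),
            ("B", "NotoPeninsula", 1, 2015, np.nan, -0.3, -8.0, 340.0),
            ("C", "PacificOffshore", 0, 2015, np.nan, -0.1, -8.0, 320.0),
        ]
        out = assign_by_threshold(make_table(rows), self.RULES).set_index("fish_id")
        assert out.loc["A", "label"] == "local" and out.loc["A", "label_source"] == "fixed"
        assert out.loc["B", "label"] == "unclassified"
        assert out.loc["C", "label"] == "pacific_offshore"

    def test_missing_rule_for_year_class_errors(self):
        rows = [("A", "OkiIslands", 1, 2014, -0.5, -0.3, -8.0, 340.0)]
        with pytest.raises(KeyError, match="2014"):
            assign_by_threshold(make_table(rows), self.RULES)

    def test_idempotent_and_order_independent(self, stage_table):
        rules = compute_thresholds(stage_table)
        once = assign_by_threshold(stage_table, rules)
        twice = assign_by_threshold(once, rules)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = stage_table.sample(frac=1, random_state=0)
        out_shuffled = assign_by_threshold(shuffled, rules).sort_values("fish_id")
        pd.testing.assert_series_equal(
            out_shuffled.set_index("fish_id")["label"],
            once.sort_values("fish_id").set_index("fish_id")["label"],
        )


def _two_class_table(n_per_class=20, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_per_class):
        rows.append((f"L{i}", "OkiIslands", 1, 2015, -1.5, *rng.normal([0, 0, 0], 1)))
        rows.append((f"N{i}", "OkiIslands", 1, 2015, -0.1, *rng.normal([sep] * 3, 1)))
    df = make_table(rows)
    return assign_by_threshold(df, {2015: ThresholdRule(2015, -0.9, 4)})


class TestLda:
    def test_well_separated_classes(self):
        df = _two_class_table()
        model = fit_lda(df)
        assert model.predict(np.array([[1.0, 1.0, 1.0]]))[0] == "local"
        assert model.predict(np.array([[9.0, 9.0, 9.0]]))[0] == "nonlocal"

    def test_identical_means_decided_by_priors(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(30):
            rows.append((f"L{i}", "OkiIslands", 1, 2015, -1.5, *rng.normal(0, 1, 3)))
        for i in range(10):
            rows.append((f"N{i}", "OkiIslands", 1, 2015, -0.1, *rng.normal(0, 1, 3)))
        df = assign_by_threshold(make_table(rows), {2015: ThresholdRule(2015, -0.9, 4)})
        model = fit_lda(df)
        model.means[1] = model.means[0]  # force exactly identical means
        model.__post_init__()
        X = rng.normal(0, 1, size=(50, 3))
        assert (model.predict(X) == "local").all()  # majority-class prior wins

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(2)
        agree = total = 0
        for trial in range(10):
            df = _two_class_table(n_per_class=15, sep=1.0, seed=trial)
            model = fit_lda(df)
            learn = df[provenance.learning_mask(df)]
            X = learn[list(model.features)].to_numpy(float)
            y = learn["label"].to_numpy()
            ref = sklearn.LinearDiscriminantAnalysis(priors=model.priors).fit(X, y)
            Xq = rng.normal(0.5, 1.5, size=(100, 3))
            agree += (model.predict(Xq) == ref.predict(Xq)).sum()
            total += 100
        assert agree / total >= 0.99

    def test_singular_covariance_detected(self):
        df = _two_class_table()
        df["larval_d13C"] = df["larval_d18O"]  # duplicated feature
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(df)


class TestLoocv:
    def test_perfect_separation_gives_accuracy_one(self):
        rep = loocv(_two_class_table(sep=10.0))
        assert rep.accuracy == 1.0

    def test_chance_level_on_uninformative_features(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(200, 3))
        rows = []
        for i in range(200):
            juv = -1.5 if i % 2 == 0 else -0.1  # labels unrelated to features
            rows.append((f"F{i}", "OkiIslands", 1, 2015, juv, *X[i]))
        df = assign_by_threshold(make_table(rows), {2015: ThresholdRule(2015, -0.9, 4)})
        rep = loocv(df)
        # binomial 99% band around 0.5 at n=200 is ~ +/- 0.09
        assert 0.40 <= rep.accuracy <= 0.60

    def test_prediction_counts_sum_to_n(self, labeled_table):
        rep = loocv(labeled_table)
        assert rep.per_predicted["n_predicted"].sum() == rep.n

    def test_singleton_class_fold_skipped(self):
        df = _two_class_table(n_per_class=6)
        df = pd.concat([df[df["label"] == "local"], df[df["label"] == "nonlocal"].head(2)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = loocv(df.reset_index(drop=True))
        assert rep.n_skipped == 2  # both nonlocal folds undefined
        assert rep.n == len(df) - 2


class TestClassifyUnlabeled:
    def test_boundary_tie_breaks_local(self):
        # symmetric model: the origin scores exactly equally for both classes
        model = provenance.DiscriminantModel(
            classes=("local", "nonlocal"),
            means=np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            pooled_cov=np.eye(3),
            priors=np.array([0.5, 0.5]),
        )
        assert model.predict(np.zeros((1, 3)))[0] == "local"

    def test_learning_set_predictions_consistent_and_never_overwritten(self, labeled_table):
        model = fit_lda(labeled_table)
        out = classify_unlabeled(model, labeled_table)
        pre = labeled_table["label"] != "unclassified"
        assert (out.loc[pre, "label"] == labeled_table.loc[pre, "label"]).all()

    def test_all_complete_unclassified_fish_get_labels(self, labeled_table):
        model = fit_lda(labeled_table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = classify_unlabeled(model, labeled_table)
        todo = labeled_table["label"] == "unclassified"
        complete = labeled_table[list(model.features)].notna().all(axis=1)
        relabeled = (out["label_source"] == "lda").sum()
        assert relabeled == (todo & complete).sum()
        assert (out.loc[todo & ~complete, "label"] == "unclassified").all()


class TestProportions:
    def _labeled(self, counts):
        rows, i = [], 0
        for label, n in counts.items():
            for _ in range(n):
                rows.append({"region": "OkiIslands", "year_class": 2015, "label": label,
                             "label_source": "threshold", "capture_date": pd.Timestamp("2016-02-10")})
                i += 1
        return pd.DataFrame(rows)

    def test_one_in_five_is_twenty_percent(self):
        df = self._labeled({"nonlocal": 1, "local": 4})
        out = proportions_by_group(df, ("region",))
        assert out.loc[0, "pct_nonlocal"] == pytest.approx(20.0)

    def test_all_nonlocal_is_hundred_percent(self):
        df = self._labeled({"nonlocal": 13})
        out = proportions_by_group(df, ("region",))
        assert out.loc[0, "pct_nonlocal"] == pytest.approx(100.0)

    def test_group_with_no_definite_labels_flagged(self):
        df = self._labeled({"unclassified": 3})
        out = proportions_by_group(df, ("region",))
        assert np.isnan(out.loc[0, "pct_nonlocal"]) and not out.loc[0, "pct_defined"]

    def test_capture_month_grouping(self):
        df = self._labeled({"nonlocal": 2, "local": 2})
        df.loc[:1, "capture_date"] = pd.Timestamp("2016-05-01")
        out = proportions_by_group(df, ("capture_month",))
        assert set(out["capture_month"]) == {2, 5}


def test_full_recovery_on_default_cohort(labeled_table, truth_by_fish):
    """Threshold plus discriminant recovers the simulated provenance for at
    least 90% of juvenile-measured fish and 75% of discriminant-only fish."""
    model = fit_lda(labeled_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = classify_unlabeled(model, labeled_table)
    merged = final.merge(truth_by_fish.rename("true_label"), left_on="fish_id", right_index=True)
    juv = merged[merged["juvenile_d18O"].notna() & (merged["region"] != "PacificOffshore")]
    assert (juv["label"] == juv["true_label"]).mean() >= 0.90
    lda_only = merged[merged["label_source"] == "lda"]
    assert (lda_only["label"] == lda_only["true_label"]).mean() >= 0.75
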