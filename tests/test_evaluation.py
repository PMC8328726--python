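"""Repeated-split protocol, AUC, and family-comparison behavior."""

import numpy as np
import pandas as pd
import pytest

from mritex.evaluation import (
    Classifier,
    EvalProtocol,
    auc,
    family_comparison,
    repeated_split_eval,
)
from oracles import auc_oracle


def test_auc_perfect_ordering():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auc_all_ties_is_half():
    assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5


def test_auc_hand_case():
    assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


def test_auc_matches_pair_counting_oracle(rng):
    for n in (5, 20, 80, 200):
        scores = rng.integers(0, 10, size=n) / 10.0  # many ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc(scores, labels) == auc_oracle(scores, labels)


def separable_data(n=40):
    y = np.repeat([0, 1], n // 2)
    X = y.astype(float)[:, None]
    return X, y


def test_separable_feature_perfect_accuracy():
    X, y = separable_data()
    res = repeated_split_eval(X, y, EvalProtocol(repeats=100, seed=0))
    assert res.mean_accuracy == 1.0
    assert res.mean_auc == 1.0


def test_permuted_labels_chance_level(rng):
    X = rng.standard_normal((60, 5))
    y = np.repeat([0, 1], 30)
    res = repeated_split_eval(X, rng.permutation(y), EvalProtocol(repeats=100, seed=1))
    assert abs(res.mean_accuracy - 0.5) < 0.06


def test_duplicate_columns_equivalent_accuracy():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((50, 3)) + np.repeat([0, 1], 25)[:, None]
    y = np.repeat([0, 1], 25)
    a = repeated_split_eval(X, y, EvalProtocol(repeats=30, seed=2))
    b = repeated_split_eval(np.hstack([X, X]), y, EvalProtocol(repeats=30, seed=2))
    np.testing.assert_allclose(a.accuracies, b.accuracies, atol=1e-6)


def test_summary_matches_raw_scores():
    X, y = separable_data()
    X = X + np.random.default_rng(3).standard_normal(X.shape) * 0.8
    res = repeated_split_eval(X, y, EvalProtocol(repeats=25, seed=4))
    assert res.mean_accuracy == res.accuracies.mean()
    assert res.std_accuracy == res.accuracies.std()
    assert res.mean_auc == res.aucs.mean()
    assert len(res.accuracies) == len(res.split_seeds) == 25


def test_nan_rows_dropped_and_counted():
    X, y = separable_data(40)
    X = np.hstack([X, np.ones((40, 1))])
    X[3, 1] = np.nan
    X[17, 1] = np.nan
    res = repeated_split_eval(X, y, EvalProtocol(repeats=5, seed=0))
    assert res.n_dropped_rows == 2


def test_single_class_and_tiny_cohorts_rejected():
    with pytest.raises(ValueError):
        repeated_split_eval(np.zeros((10, 2)), np.zeros(10), EvalProtocol(repeats=2))
    with pytest.raises(ValueError):
        repeated_split_eval(
            np.zeros((6, 2)), np.array([0, 0, 0, 1, 1, 1]), EvalProtocol(repeats=2)
        )


@pytest.mark.parametrize("clf", list(Classifier))
def test_all_classifiers_run(clf):
    X, y = separable_data()
    X = X + 0.01 * np.random.default_rng(0).standard_normal(X.shape)
    res = repeated_split_eval(X, y, EvalProtocol(repeats=5, seed=0, classifier=clf))
    assert res.mean_accuracy == 1.0


def test_repeat_determinism():
    X, y = separable_data()
    X = X + np.random.default_rng(5).standard_normal(X.shape)
    a = repeated_split_eval(X, y, EvalProtocol(repeats=1, seed=9))
    b = repeated_split_eval(X, y, EvalProtocol(repeats=1, seed=9))
    np.testing.assert_array_equal(a.accuracies, b.accuracies)
    np.testing.assert_array_equal(a.split_seeds, b.split_seeds)


def test_informative_family_outranks_noise(rng):
    n = 60
    y = np.repeat([0, 1], n // 2)
    table = pd.DataFrame(
        {
            "sig_1": y + 0.3 * rng.standard_normal(n),
            "sig_2": y + 0.3 * rng.standard_normal(n),
            "noise_1": rng.standard_normal(n),
            "noise_2": rng.standard_normal(n),
        }
    )
    fams = {"informative": ["sig_1", "sig_2"], "noise": ["noise_1", "noise_2"]}
    report = family_comparison(table, y, EvalProtocol(repeats=100, seed=6), families=fams)
    assert report.ranking[0] == "informative"
    assert report.results["informative"].mean_accuracy > 0.9
    # noise features can retain spurious in-sample correlation under
    # resampled splits; require only a clear gap to the informative family
    assert report.results["noise"].mean_accuracy < 0.75
    assert (
        report.results["informative"].mean_accuracy
        - report.results["noise"].mean_accuracy
        > 0.2
    )


def test_all_families_beat_best_single_with_independent_signal(rng):
    n = 80
    y = np.repeat([0, 1], n // 2)
    f1 = y + 1.2 * rng.standard_normal(n)
    f2 = y + 1.2 * rng.standard_normal(n)
    table = pd.DataFrame({"f1": f1, "f2": f2})
    fams = {"fam1": ["f1"], "fam2": ["f2"], "all": ["f1", "f2"]}
    report = family_comparison(table, y, EvalProtocol(repeats=100, seed=7), families=fams)
    best_single = max(report.results["fam1"].mean_auc, report.results["fam2"].mean_auc)
    assert report.results["all"].mean_auc >= best_single - 0.02


def test_family_comparison_needs_two_families():
    table = pd.DataFrame({"a": [0, 1, 0, 1]})
    with pytest.raises(ValueError):
        family_comparison(table, [0, 1, 0, 1], families={"one": ["a"]})


def test_class_gap_monotonicity():
    """Widening the class gap never decreases ALL-family accuracy."""
    import mritex as mx
    from mritex.features import cohort_feature_table

    accs = []
    for gap in (0.25, 0.6, 1.0):
        cohort = mx.generate_cohort(12, mx.default_spec(class_gap=gap), seed=21)
        table = cohort_feature_table(
            [s.image for s in cohort], [s.lesion_mask for s in cohort]
        )
        labels = [s.label for s in cohort]
        res = repeated_split_eval(
            table[table.attrs["families"]["all"]].to_numpy(),
            labels,
            EvalProtocol(repeats=40, seed=8),
        )
        accs.append(res.mean_accuracy)
    assert accs[1] >= accs[0] - 0.05
    assert accs[2] >= accs[1] - 0.05
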