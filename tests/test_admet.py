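from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu
from sklearn.metrics import roc_auc_score

from erainv.admet import (
    compare_single_vs_multi,
    evaluate_admet,
    mannwhitney_compare,
    predict_admet,
    train_admet,
)
from erainv.data_model import ConfigError
from erainv.metrics import UndefinedMetricError, accuracy, roc_auc


@pytest.fixture(scope="module")
def toy_admet():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(300, 6)),
                     columns=[f"d{j}" for j in range(6)])
    logits = X.to_numpy() @ rng.normal(size=(6, 5)) * 2.0
    Y = (logits + rng.logistic(size=(300, 5)) > 0).astype(int)
    # ensure both classes everywhere
    Y[0] = 0
    Y[1] = 1
    return X, Y


# ---------------------------------------------------------------------------
# Metrics


def test_auc_hand_example():
    # 3 of 4 positive-negative pairs correctly ordered
    assert roc_auc(np.array([1, 0, 1, 0]),
                   np.array([0.9, 0.8, 0.3, 0.2])) == pytest.approx(0.75)


def test_auc_perfect_separation():
    assert roc_auc(np.array([1, 1, 0, 0]),
                   np.array([0.9, 0.8, 0.3, 0.2])) == 1.0


def test_auc_constant_scores_half():
    assert roc_auc(np.array([1, 0, 1, 0, 1]), np.full(5, 0.4)) == 0.5


def test_auc_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        roc_auc(np.ones(4), np.linspace(0, 1, 4))


def test_acc_and_auc_match_independent_implementations():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(4, 60))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        scores = np.round(rng.uniform(size=n), 2)    # induce ties
        pred = (scores > 0.5).astype(int)
        assert accuracy(y, pred) == pytest.approx(np.mean(y == pred), abs=1e-15)
        assert roc_auc(y, scores) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_separated_samples_exact_p():
    res = mannwhitney_compare([1, 2, 3], [4, 5, 6])
    assert res.u_a == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "exact"


def test_mwu_identical_samples():
    res = mannwhitney_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.u_a == pytest.approx(4.5)          # n^2/2
    assert res.p_value == pytest.approx(1.0)


def test_mwu_u_identity():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.normal(size=int(rng.integers(1, 12)))
        b = rng.normal(size=int(rng.integers(1, 12)))
        res = mannwhitney_compare(a, b)
        assert res.u_a + res.u_b == pytest.approx(len(a) * len(b))


def test_mwu_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(3)
    for na in range(1, 7):
        for nb in range(1, 7):
            pooled = rng.permutation(np.arange(na + nb, dtype=float))
            a, b = pooled[:na], pooled[na:]
            res = mannwhitney_compare(a, b)
            ref = scipy_mwu(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12), (na, nb)


def test_mwu_exact_matches_independent_enumeration_with_ties():
    """Tie-aware exact p cross-checked against a from-scratch enumeration."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(4)
    for _ in range(10):
        na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        a = rng.integers(0, 3, size=na).astype(float)
        b = rng.integers(0, 3, size=nb).astype(float)
        res = mannwhitney_compare(a, b)
        ranks = rankdata(np.concatenate([a, b]))
        mu = na * nb / 2
        u_obs = ranks[:na].sum() - na * (na + 1) / 2
        total = count = 0
        for combo in combinations(range(na + nb), na):
            u = ranks[list(combo)].sum() - na * (na + 1) / 2
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)


def test_mwu_normal_approximation_large_samples():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 30)
    b = rng.normal(1.2, 1, 30)
    res = mannwhitney_compare(a, b)
    assert res.method == "normal"
    ref = scipy_mwu(a, b, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)
    assert res.significant


def test_mwu_empty_sample_rejected():
    with pytest.raises(ConfigError):
        mannwhitney_compare([], [1.0])


# ---------------------------------------------------------------------------
# Models


def test_train_modes_deterministic(toy_admet):
    X, Y = toy_admet
    for mode in ("single", "multi"):
        m1 = train_admet(X, Y, mode=mode, seed=3)
        m2 = train_admet(X, Y, mode=mode, seed=3)
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))


def test_labels_strictly_exceed_threshold(toy_admet):
    X, Y = toy_admet
    model = train_admet(X, Y, mode="multi", seed=0)
    probs, labels = predict_admet(model, X)
    np.testing.assert_array_equal(labels, (probs > 0.5).astype(int))
    # probability exactly at the threshold maps to class 0
    model.threshold = probs[0, 0]
    _, labels2 = predict_admet(model, X)
    assert labels2[0, 0] == 0


def test_bad_label_shapes_rejected(toy_admet):
    X, Y = toy_admet
    with pytest.raises(ConfigError):
        train_admet(X, Y[:, :4], mode="multi", seed=0)
    with pytest.raises(ConfigError):
        train_admet(X, Y + 1, mode="multi", seed=0)
    Y_single = Y.copy()
    Y_single[:, 2] = 0
    with pytest.raises(ConfigError, match="hERG"):
        train_admet(X, Y_single, mode="multi", seed=0)


def test_evaluate_admet_reports_five_properties(toy_admet):
    X, Y = toy_admet
    model = train_admet(X, Y, mode="multi", seed=0)
    metrics = evaluate_admet(model, X, Y)
    assert len(metrics.properties) == 5
    assert np.all((metrics.acc >= 0) & (metrics.acc <= 1))
    assert np.all((metrics.auc >= 0) & (metrics.auc <= 1))


def test_compare_single_vs_multi_modes_agree(toy_admet):
    X, Y = toy_admet
    report = compare_single_vs_multi(X, Y, reps=5, seed=0)
    assert report.reps == 5
    assert len(report.results) == 5
    # the two boosted backends agree within 0.05 held-out ACC per property
    gap = np.abs(report.acc_multi.mean(axis=0) - report.acc_single.mean(axis=0))
    assert np.all(gap < 0.05)
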