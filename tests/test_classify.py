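"""Kennard-Stone splitting and the five classifiers (with brute-force and
closed-form oracles)."""

import itertools

import numpy as np
import pytest

from conftest import subset_matrix
from crpkit.classify import (UNASSIGNED, CARTClassifier, KNNClassifier,
                             PLSDAClassifier, SIMCAClassifier, SVMDAClassifier,
                             _kennard_stone_select, classifier_from_dict,
                             kennard_stone_split, make_classifier, select_k_loo)
from crpkit.preprocess import PreprocessRecipe


# ---------------------------------------------------------------------------
# Kennard-Stone
# ---------------------------------------------------------------------------

def test_ks_study_scale_split_sizes():
    """Per-class 60% ceiling on 38 + 49 samples -> 23 + 30 calibration."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(87, 10))
    y = np.array(["RH"] * 38 + ["RA"] * 49, dtype=object)
    res = kennard_stone_split(X, y, fraction=0.6, per_class=True)
    assert res.per_class == {"RH": (23, 15), "RA": (30, 19)}
    assert res.calibration.size == 53 and res.validation.size == 34
    assert set(res.calibration) | set(res.validation) == set(range(87))
    assert set(res.calibration) & set(res.validation) == set()


def test_ks_collinear_picks_extremes_then_center():
    X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
    assert _kennard_stone_select(X, 3) == [0, 4, 2]


def test_ks_boundary_and_errors():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array(["A", "A", "A"], dtype=object)
    with pytest.warns(UserWarning, match="empty validation"):
        res = kennard_stone_split(X, y, fraction=0.99, per_class=True)
    assert res.validation.size == 0
    with pytest.raises(ValueError):
        kennard_stone_split(X, y, fraction=1.5)
    with pytest.raises(ValueError, match="at least 2"):
        kennard_stone_split(X, np.array(["A", "A", "B"], dtype=object), fraction=0.6)


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(7)
    X0 = rng.normal(0, 0.3, size=(12, 6)) + np.array([3, 0, 0, 0, 0, 0])
    X1 = rng.normal(0, 0.3, size=(14, 6)) + np.array([0, 3, 0, 0, 0, 0])
    X = np.vstack([X0, X1])
    y = np.array(["RH"] * 12 + ["RA"] * 14, dtype=object)
    return X, y


ALL_KINDS = [("plsda", {"n_latent": 2}), ("knn", {"k": 3}),
             ("simca", {"n_pcs": 2, "alpha": 0.05}), ("cart", {}), ("svmda", {})]


@pytest.mark.parametrize("kind,params", ALL_KINDS)
def test_predictions_deterministic_and_permutation_invariant(kind, params, separable):
    X, y = separable
    rng = np.random.default_rng(0)
    perm = rng.permutation(X.shape[0])
    a = make_classifier(kind, **params).fit(X, y)
    b = make_classifier(kind, **params).fit(X[perm], y[perm])
    q = rng.normal(0, 1, size=(10, 6))
    assert np.array_equal(a.predict(q), a.predict(q))  # pure / deterministic
    assert np.array_equal(a.predict(q), b.predict(q))


@pytest.mark.parametrize("kind,params", ALL_KINDS)
def test_only_simca_may_unassign(kind, params, separable):
    X, y = separable
    model = make_classifier(kind, **params).fit(X, y)
    far = np.full((4, 6), 50.0)
    preds = set(model.predict(np.vstack([X, far])))
    if kind == "simca":
        assert preds <= {"RH", "RA", UNASSIGNED}
    else:
        assert preds <= {"RH", "RA"}


@pytest.mark.parametrize("kind,params", ALL_KINDS)
def test_serialization_round_trip(kind, params, separable):
    X, y = separable
    model = make_classifier(kind, **params).fit(X, y)
    clone = classifier_from_dict(model.to_dict())
    q = np.random.default_rng(1).normal(size=(8, 6))
    assert np.array_equal(model.predict(q), clone.predict(q))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def test_plsda_separable_calibration_perfect(separable):
    X, y = separable
    model = PLSDAClassifier(n_latent=2).fit(X, y)
    assert np.array_equal(model.predict(X), y)


def test_plsda_full_rank_equals_least_squares():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 4))
    y01 = (rng.normal(size=12) > 0).astype(float)
    y = np.where(y01 == 1, "B", "A")
    model = PLSDAClassifier(n_latent=4).fit(X, y)
    Xc = X - X.mean(axis=0)
    beta = np.linalg.lstsq(Xc, y01 - y01.mean(), rcond=None)[0]
    ols = Xc @ beta + y01.mean()
    assert np.allclose(model.decision_values(X), ols, atol=1e-8)


def test_plsda_single_class_errors():
    with pytest.raises(ValueError, match="single class"):
        PLSDAClassifier().fit(np.eye(4), ["A"] * 4)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def test_knn_k1_resubstitution_perfect(separable):
    X, y = separable
    model = KNNClassifier(k=1).fit(X, y)
    assert np.array_equal(model.predict(X), y)


def test_knn_matches_brute_force_vote():
    X = np.array([[0.0], [1.0], [4.0], [5.0]])
    y = np.array(["A", "A", "B", "B"], dtype=object)
    model = KNNClassifier(k=3).fit(X, y)
    queries = np.array([[0.5], [2.4], [2.6], [4.9]])
    for q, pred in zip(queries, model.predict(queries)):
        dist = np.abs(X[:, 0] - q[0])
        nn = np.argsort(dist, kind="stable")[:3]
        votes = {}
        for t in nn:
            votes[y[t]] = votes.get(y[t], 0) + 1
        assert pred == max(votes, key=votes.get)


def test_knn_errors_and_loo_selection(separable):
    X, y = separable
    with pytest.raises(ValueError):
        KNNClassifier(k=26).fit(X, y)
    # perfectly separated classes: every K works; ties -> smallest K
    assert select_k_loo(X, y, [1, 3, 5]) == 1
    assert select_k_loo(X, y, [3, 5]) == 3


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

def test_simca_accepts_own_training_rows():
    rng = np.random.default_rng(2)
    X0 = rng.normal(0, 1.0, size=(20, 30)) + 5
    X1 = rng.normal(0, 1.0, size=(20, 30)) - 5
    X = np.vstack([X0, X1])
    y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
    model = SIMCAClassifier(n_pcs=2, alpha=0.01).fit(X, y)
    # a query identical to a class-A training row is assigned to A
    assert model.predict(X0[:5]).tolist() == ["A"] * 5


def test_simca_collinear_class_rejects_off_line_queries():
    """Three collinear points with one PC have zero calibration residual;
    any off-line query is rejected by that class."""
    A = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    B = np.array([[10.0, 0.0], [11.0, 0.5], [12.0, -0.5], [13.0, 0.2]])
    X = np.vstack([A, B])
    y = np.array(["A"] * 3 + ["B"] * 4, dtype=object)
    model = SIMCAClassifier(n_pcs=1, alpha=0.05).fit(X, y)
    # the A model's calibration residual variance is (numerically) zero, so
    # its acceptance region collapses: off-line queries are rejected by A
    assert model._models["A"]["s0_sq"] == pytest.approx(0.0, abs=1e-20)
    ratios = model.f_ratios(np.array([[1.0, 2.0]]))  # off the A line
    assert ratios["A"][0] > model._models["A"]["crit"]
    on_line = model.f_ratios(np.array([[1.5, 1.5]]))
    assert on_line["A"][0] <= model._models["A"]["crit"]


def test_simca_unassigned_for_alien_queries(separable):
    X, y = separable
    model = SIMCAClassifier(n_pcs=2, alpha=0.05).fit(X, y)
    alien = np.full((3, 6), 40.0)
    assert model.predict(alien).tolist() == [UNASSIGNED] * 3


def test_simca_npcs_validation(separable):
    X, y = separable
    with pytest.raises(ValueError, match="class size"):
        SIMCAClassifier(n_pcs=12).fit(X, y)
    per_class = SIMCAClassifier(n_pcs={"RH": 2, "RA": 3}).fit(X, y)
    assert per_class._models["RA"]["k"] == 3


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

def test_cart_single_split_on_perfect_feature():
    X = np.column_stack([np.r_[np.zeros(5), np.ones(5)],
                         np.random.default_rng(0).normal(size=10)])
    y = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
    model = CARTClassifier().fit(X, y)
    assert np.array_equal(model.predict(X), y)
    assert model.tree_.max_depth == 1
    # parent Gini 0.5 splits to two pure children
    assert model.tree_.impurity[0] == pytest.approx(0.5)
    assert model.tree_.impurity[1] == model.tree_.impurity[2] == 0.0


def test_cart_best_split_matches_exhaustive_search():
    X = np.array([[1.0, 7.0], [2.0, 1.0], [3.0, 8.0],
                  [6.0, 2.0], [7.0, 9.0], [8.0, 3.0]])
    y = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
    model = CARTClassifier().fit(X, y)

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return 1 - (p ** 2).sum()

    best = None
    for f in range(2):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            w = (len(left) * gini(left) + len(right) * gini(right)) / len(y)
            if best is None or w < best[0] - 1e-12:
                best = (w, f, thr)
    assert model.tree_.feature[0] == best[1]
    assert model.tree_.threshold[0] == pytest.approx(best[2])


def test_cart_requires_two_classes():
    with pytest.raises(ValueError):
        CARTClassifier().fit(np.eye(3), ["A"] * 3)


# ---------------------------------------------------------------------------
# SVM-DA
# ---------------------------------------------------------------------------

def test_svmda_two_point_margin_analytic():
    """Hard-margin solution for points -1/+1: boundary at 0, |w| = 1,
    margin width 2, both points support vectors."""
    model = SVMDAClassifier(C=1e6).fit(np.array([[-1.0], [1.0]]), ["A", "B"])
    svc = model.svc_
    assert svc.coef_[0][0] == pytest.approx(1.0, rel=1e-6)
    assert svc.intercept_[0] == pytest.approx(0.0, abs=1e-9)
    assert 2 / abs(svc.coef_[0][0]) == pytest.approx(2.0, rel=1e-6)
    assert len(svc.support_) == 2


def test_svmda_separable_perfect_and_degenerate_no_error(separable):
    X, y = separable
    model = SVMDAClassifier().fit(X, y)
    assert np.array_equal(model.predict(X), y)
    # conflicting duplicate labels at one point: soft margin still fits
    Xd = np.array([[0.0], [0.0], [1.0], [1.0]])
    yd = np.array(["A", "B", "A", "B"], dtype=object)
    SVMDAClassifier().fit(Xd, yd).predict(Xd)
    with pytest.raises(ValueError):
        SVMDAClassifier().fit(np.eye(3), ["A"] * 3)


# ---------------------------------------------------------------------------
# Benchmark behaviour (reduced-resolution)
# ---------------------------------------------------------------------------

def test_benchmark_validation_accuracies(small_benchmark):
    """On a noisy two-class fingerprint benchmark the distance/covariance
    models separate the classes perfectly after SNV + centering."""
    m = small_benchmark
    res = kennard_stone_split(m, fraction=0.6)
    cal_raw, val_raw = subset_matrix(m, res.calibration), subset_matrix(m, res.validation)
    recipe = PreprocessRecipe(["snv", "mean_center"])
    cal = recipe.fit_transform(cal_raw)
    val = recipe.transform(val_raw)
    y_cal, y_val = cal.labels_array(), val.labels_array()
    for kind, params in [("knn", {"k": 3}), ("plsda", {"n_latent": 2}), ("svmda", {})]:
        model = make_classifier(kind, **params).fit(cal.X, y_cal)
        assert np.array_equal(model.predict(val.X), y_val), kind
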