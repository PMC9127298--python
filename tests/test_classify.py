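import numpy as np
import pytest

from holospect.classify import (
    FeatureMatrix, FeatureSpec, GentleBoostClassifier, LogitBoostClassifier,
    SelectionConfig, build_features, compute_metrics, iterative_selection,
    logitboost_rank, make_algorithms, prune_correlated, train_and_evaluate,
)


def separable_matrix(n=40, n_features=10, informative=3, seed=0, shift=2.0):
    """Gaussian features; one feature carries a clean class shift."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = rng.normal(size=(n, n_features))
    x[:, informative] += shift * y
    specs = [FeatureSpec("component", (0, 0, i)) for i in range(n_features)]
    return FeatureMatrix(values=x, specs=specs, labels=y)


# ----------------------------------------------------------------- metrics

def test_compute_metrics_identities():
    m = compute_metrics(tp=30, fn=10, tn=45, fp=15)
    assert m["sensitivity"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(0.75)
    assert m["precision"] == pytest.approx(30 / 45)
    assert m["accuracy"] == pytest.approx(75 / 100)
    # accuracy is the prevalence-weighted mean of sensitivity and specificity
    p, n = 40, 60
    assert m["accuracy"] == pytest.approx(
        (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
    )
    assert m["f1"] == pytest.approx(2 * 30 / (2 * 30 + 15 + 10))


def test_compute_metrics_masks_undefined():
    m = compute_metrics(tp=0, fn=0, tn=5, fp=0)
    assert np.isnan(m["sensitivity"])
    assert m["specificity"] == 1.0


# ---------------------------------------------------------------- features

def test_build_features_shapes(rng):
    spectra = rng.lognormal(size=(8, 2, 3, 4))
    labels = np.array([0, 1] * 4)
    comp = build_features(spectra, labels, universe="component")
    assert comp.values.shape == (8, 24)
    both = build_features(spectra, labels, universe="both")
    assert both.values.shape == (8, 24 + 24 * 23 // 2)
    cells = [(0, 0, 0), (1, 2, 3)]
    sub = build_features(spectra, labels, universe="both", cells=cells)
    assert sub.values.shape == (8, 3)
    assert sub.specs[2].kind == "ratio"
    assert np.allclose(
        sub.values[:, 2], spectra[:, 0, 0, 0] / spectra[:, 1, 2, 3]
    )


def test_ratio_denominator_floor():
    spectra = np.zeros((4, 1, 1, 2))
    spectra[:, 0, 0, 0] = 1.0
    fm = build_features(spectra, np.array([0, 1, 0, 1]), universe="ratio")
    assert np.isfinite(fm.values).all()


def test_prune_correlated_drops_duplicates(rng):
    x = rng.normal(size=(30, 3))
    dup = np.column_stack([x, x[:, 0] * 2.0 + 1e-9])  # perfect duplicate
    specs = [FeatureSpec("component", (0, 0, i)) for i in range(4)]
    fm = FeatureMatrix(dup, specs, np.array([0, 1] * 15))
    pruned = prune_correlated(fm)
    assert pruned.n_features == 3
    again = prune_correlated(pruned)
    assert again.n_features == 3  # idempotent


# ---------------------------------------------------------------- boosting

def test_logitboost_fits_separable_data():
    fm = separable_matrix()
    model = LogitBoostClassifier(n_rounds=30).fit(fm.values, fm.labels)
    assert (model.predict(fm.values) == fm.labels).mean() == 1.0
    imp = model.feature_importances_
    assert np.argmax(imp) == 3


def test_gentleboost_fits_separable_data():
    fm = separable_matrix(seed=1)
    model = GentleBoostClassifier(n_rounds=30).fit(fm.values, fm.labels)
    assert (model.predict(fm.values) == fm.labels).mean() == 1.0


def test_boosting_deterministic():
    fm = separable_matrix(seed=2)
    d1 = LogitBoostClassifier(n_rounds=20).fit(fm.values, fm.labels) \
        .decision_function(fm.values)
    d2 = LogitBoostClassifier(n_rounds=20).fit(fm.values, fm.labels) \
        .decision_function(fm.values)
    assert np.array_equal(d1, d2)


def test_rank_puts_informative_feature_first():
    fm = separable_matrix(seed=3)
    ranked = logitboost_rank(fm)
    assert ranked[0] == 3


# ---------------------------------------------------------------- selection

def test_iterative_selection_recovers_planted_features(rng):
    n, n_feat = 60, 250
    y = np.array([0, 1] * (n // 2))
    x = rng.normal(size=(n, n_feat))
    planted = [17, 123, 201]
    for j in planted:
        x[:, j] += 2.5 * y
    specs = [FeatureSpec("component", (0, 0, j)) for j in range(n_feat)]
    fm = FeatureMatrix(x, specs, y)
    sel = iterative_selection(fm, SelectionConfig(chunk_size=100, final_k=3))
    chosen = {s.numerator[2] for s in sel.specs}
    assert chosen == set(planted)


def test_selection_single_short_chunk():
    fm = separable_matrix(n=30, n_features=8)
    sel = iterative_selection(fm, SelectionConfig(chunk_size=100, final_k=3))
    assert sel.n_features == 3
    assert 3 in {s.numerator[2] for s in sel.specs}


# --------------------------------------------------------------- evaluation

def test_train_and_evaluate_separable():
    fm_train = separable_matrix(n=60, seed=4, shift=3.5)
    fm_test = separable_matrix(n=30, seed=5, shift=3.5)
    report = train_and_evaluate(fm_train, fm_test, cv_folds=5, seed=0)
    assert set(report.algorithms) == {
        "LogitBoost", "Bag", "GentleBoost", "Tree", "SVM", "NaiveBayes", "KNN"
    }
    for ar in report.algorithms.values():
        assert ar.cv_auc >= 0.85
        assert ar.test_metrics["accuracy"] > 0.8


def test_train_and_evaluate_deterministic():
    fm_train = separable_matrix(n=40, seed=6)
    fm_test = separable_matrix(n=20, seed=7)
    r1 = train_and_evaluate(fm_train, fm_test, cv_folds=4, seed=9)
    r2 = train_and_evaluate(fm_train, fm_test, cv_folds=4, seed=9)
    for name in r1.algorithms:
        assert r1.algorithms[name].cv_auc == r2.algorithms[name].cv_auc
        assert r1.algorithms[name].confusion == r2.algorithms[name].confusion


def test_shuffled_labels_give_chance_auc(rng):
    # leakage guard: destroying the labels must destroy the CV AUC
    fm = separable_matrix(n=94, n_features=6, seed=8)
    shuffled = FeatureMatrix(
        fm.values, fm.specs, rng.permutation(fm.labels)
    )
    report = train_and_evaluate(shuffled, shuffled, cv_folds=10, seed=1)
    auc = report.algorithms["LogitBoost"].cv_auc
    assert 0.3 < auc < 0.7


def test_knn_capped_for_tiny_samples():
    algos = make_algorithms(seed=0, X=np.zeros((4, 2)))
    assert algos["KNN"].n_neighbors == 2
    algos_big = make_algorithms(seed=0, X=np.zeros((200, 2)))
    assert algos_big.get("KNN").n_neighbors == 5
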