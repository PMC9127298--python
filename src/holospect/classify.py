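"""Diagnostic classification from spectral features.

Feature universe: band-cell powers per channel ("component" features) and
ratios between two components.  Selection: a greedy correlation pruning at
|r| > 0.95, then chunked LogitBoost prioritisation — subsets of 100
features each contribute their 3 top-ranked features, iterated until 3
features remain.  Evaluation: seven classifier families (LogitBoost,
Bagging, GentleBoost, decision tree, RBF-SVM, Gaussian naive Bayes, k-NN)
with stratified 10-fold cross-validated ROC/AUC on the training set and
sensitivity / specificity / precision / F1 / accuracy on a held-out test
set.

LogitBoost and GentleBoost (additive logistic regression with decision
stumps) are implemented here; the remaining algorithms wrap scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

RATIO_DENOMINATOR_FLOOR = 1e-12


# ------------------------------------------------------------------ features


@dataclass(frozen=True)
class FeatureSpec:
    """A component power or a ratio of two component powers.

    Cells are (channel index, carrier band index, AM band index) on the
    trend-first AM axis.
    """

    kind: str  # "component" | "ratio"
    numerator: tuple[int, int, int]
    denominator: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("component", "ratio"):
            raise ValueError("kind must be 'component' or 'ratio'")
        if self.kind == "ratio":
            if self.denominator is None:
                raise ValueError("ratio features need a denominator cell")
            if self.denominator == self.numerator:
                raise ValueError("ratio denominator must differ from numerator")


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_subjects, n_features)
    specs: list[FeatureSpec]
    labels: np.ndarray  # (n_subjects,) class labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x features")
        if self.values.shape[1] != len(self.specs):
            raise ValueError("specs length must equal feature count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length must equal subject count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            values=self.values[:, indices],
            specs=[self.specs[i] for i in indices],
            labels=self.labels,
        )


@dataclass(frozen=True)
class SelectionConfig:
    corr_threshold: float = 0.95
    chunk_size: int = 100
    keep_per_chunk: int = 3
    final_k: int = 3
    n_rounds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must lie in (0, 1)")
        if self.keep_per_chunk >= self.chunk_size:
            raise ValueError("keep_per_chunk must be below chunk_size")


def build_features(
    spectra: np.ndarray,
    labels: np.ndarray,
    universe: str = "both",
    cells: list[tuple[int, int, int]] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix from subject band spectra.

    ``spectra`` is (subjects, channels, carrier bands, AM bands).  Component
    features are the cell powers; ratio features are undirected pairwise
    quotients (numerator at the lower flat cell index) with the denominator
    floored at 1e-12.  ``cells`` restricts the universe to a cell subset —
    the full ratio universe grows quadratically.
    """
    if universe not in ("component", "ratio", "both"):
        raise ValueError("universe must be component, ratio, or both")
    spectra = np.asarray(spectra, dtype=float)
    n_subj = spectra.shape[0]
    if cells is None:
        cells = [
            (ch, cb, ab)
            for ch in range(spectra.shape[1])
            for cb in range(spectra.shape[2])
            for ab in range(spectra.shape[3])
        ]
    comp = np.stack([spectra[:, ch, cb, ab] for ch, cb, ab in cells], axis=1)

    values_list, specs = [], []
    if universe in ("component", "both"):
        values_list.append(comp)
        specs.extend(FeatureSpec("component", cell) for cell in cells)
    if universe in ("ratio", "both"):
        n_c = len(cells)
        for i in range(n_c):
            denom = np.where(
                np.abs(comp[:, i + 1 :]) < RATIO_DENOMINATOR_FLOOR,
                RATIO_DENOMINATOR_FLOOR,
                comp[:, i + 1 :],
            )
            values_list.append(comp[:, i, None] / denom)
            specs.extend(
                FeatureSpec("ratio", cells[i], cells[j])
                for j in range(i + 1, n_c)
            )
    values = np.concatenate(values_list, axis=1) if values_list else comp[:, :0]
    return FeatureMatrix(values=values, specs=specs, labels=np.asarray(labels))


def prune_correlated(fm: FeatureMatrix, threshold: float = 0.95) -> FeatureMatrix:
    """Greedy correlation pruning in feature order.

    A feature is dropped if its |Pearson r| with any already-retained
    feature exceeds ``threshold``; constant features are dropped with a
    warning (their correlation is undefined).
    """
    x = fm.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects to compute correlations")
    sd = x.std(axis=0)
    mean = x.mean(axis=0)
    n = x.shape[0]
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant feature(s)")
    retained: list[int] = []
    z_cols: list[np.ndarray] = []  # standardised retained columns
    for j in range(x.shape[1]):
        if sd[j] == 0:
            continue
        zj = (x[:, j] - mean[j]) / sd[j]
        if z_cols:
            r = np.abs(np.stack(z_cols, axis=1).T @ zj) / n
            if (r > threshold).any():
                continue
        retained.append(j)
        z_cols.append(zj)
    return fm.select(retained)


# ----------------------------------------------------------------- boosting


def _fit_stump(
    x: np.ndarray, z: np.ndarray, w: np.ndarray
) -> tuple[int, float, float, float, float]:
    """Weighted least-squares regression stump.

    Returns (feature, threshold, left value, right value, SSE reduction).
    Ties in SSE reduction break toward the lower feature index (strict
    improvement required to switch).
    """
    n, n_feat = x.shape
    w_tot = w.sum()
    wz_tot = (w * z).sum()
    base_sse = (w * z * z).sum() - wz_tot**2 / w_tot
    best = (0, -np.inf, wz_tot / w_tot, wz_tot / w_tot, 0.0)
    best_gain = -np.inf
    for j in range(n_feat):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        ws = w[order]
        wzs = (w * z)[order]
        cw = np.cumsum(ws)
        cwz = np.cumsum(wzs)
        valid = (xs[:-1] != xs[1:]) & (cw[:-1] > 0) & (w_tot - cw[:-1] > 0)
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            left_mean = cwz[:-1] / cw[:-1]
            right_mean = (wzs.sum() - cwz[:-1]) / (w_tot - cw[:-1])
            # SSE reduction of the split vs the pooled mean
            gain = (
                cw[:-1] * left_mean**2
                + (w_tot - cw[:-1]) * right_mean**2
                - wz_tot**2 / w_tot
            )
        gain[~valid] = -np.inf
        k = int(np.argmax(gain))
        if gain[k] > best_gain + 1e-15:
            thr = 0.5 * (xs[k] + xs[k + 1])
            best = (j, thr, float(left_mean[k]), float(right_mean[k]), float(gain[k]))
            best_gain = gain[k]
    del base_sse
    return best


def _apply_stump(x, feature, threshold, left, right):
    return np.where(x[:, feature] <= threshold, left, right)


class LogitBoostClassifier(BaseEstimator, ClassifierMixin):
    """Additive logistic regression with decision stumps (LogitBoost).

    Half-step Newton updates on the binomial log-likelihood: at each round
    the working response z = (y* - p)/(p(1-p)) is fitted by a weighted
    least-squares stump with weights w = p(1-p), and half the fitted
    function is added to the score.  Feature importance is the cumulative
    weighted-SSE reduction of the stumps splitting on each feature.
    """

    def __init__(self, n_rounds: int = 100, z_max: float = 4.0):
        self.n_rounds = n_rounds
        self.z_max = z_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("LogitBoost requires exactly two classes")
        n = len(y01)
        F = np.zeros(n)
        p = np.full(n, 0.5)
        self.stumps_ = []
        self.feature_importances_ = np.zeros(X.shape[1])
        for _ in range(self.n_rounds):
            w = np.maximum(p * (1.0 - p), 1e-10)
            z = np.clip((y01 - p) / w, -self.z_max, self.z_max)
            j, thr, left, right, gain = _fit_stump(X, z, w)
            if gain <= 0:
                break
            self.stumps_.append((j, thr, 0.5 * left, 0.5 * right))
            self.feature_importances_[j] += gain
            F += _apply_stump(X, j, thr, 0.5 * left, 0.5 * right)
            p = 1.0 / (1.0 + np.exp(-2.0 * np.clip(F, -35, 35)))
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for j, thr, left, right in self.stumps_:
            F += _apply_stump(X, j, thr, left, right)
        return F

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class GentleBoostClassifier(BaseEstimator, ClassifierMixin):
    """Gentle adaptive boosting with regression stumps on ±1 labels."""

    def __init__(self, n_rounds: int = 100):
        self.n_rounds = n_rounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("GentleBoost requires exactly two classes")
        ypm = 2.0 * y01 - 1.0
        n = len(ypm)
        w = np.full(n, 1.0 / n)
        self.stumps_ = []
        for _ in range(self.n_rounds):
            j, thr, left, right, gain = _fit_stump(X, ypm, w)
            if gain <= 0:
                break
            f = _apply_stump(X, j, thr, left, right)
            self.stumps_.append((j, thr, left, right))
            w = w * np.exp(-ypm * f)
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w /= total
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for j, thr, left, right in self.stumps_:
            F += _apply_stump(X, j, thr, left, right)
        return F

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


# ---------------------------------------------------------------- selection


def logitboost_rank(
    fm: FeatureMatrix, labels: np.ndarray | None = None, n_rounds: int = 100
) -> np.ndarray:
    """Features ranked by LogitBoost importance (descending).

    Importance is the total weighted-SSE reduction attributed to stumps
    splitting on the feature; unused features follow in index order.
    Deterministic given the data order.
    """
    labels = fm.labels if labels is None else np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("ranking requires exactly two classes")
    model = LogitBoostClassifier(n_rounds=n_rounds).fit(fm.values, labels)
    imp = model.feature_importances_
    # stable sort on (-importance, index): ties break toward lower index
    return np.argsort(-imp, kind="stable")


def iterative_selection(
    fm: FeatureMatrix,
    cfg: SelectionConfig | None = None,
) -> FeatureMatrix:
    """Chunked LogitBoost prioritisation down to ``final_k`` features.

    Features are partitioned into consecutive chunks of ``chunk_size``
    (the last chunk may be short); the top ``keep_per_chunk`` of each chunk
    survive; the procedure repeats on the survivors until at most
    ``final_k`` remain, with a final ranking pass keeping exactly
    ``final_k``.
    """
    cfg = cfg or SelectionConfig()
    if fm.n_features < cfg.final_k:
        raise ValueError("fewer features than final_k")
    current = fm
    while current.n_features > cfg.final_k:
        survivors: list[int] = []
        for start in range(0, current.n_features, cfg.chunk_size):
            idx = np.arange(start, min(start + cfg.chunk_size, current.n_features))
            chunk = current.select(idx)
            k = min(cfg.keep_per_chunk, len(idx))
            ranked = logitboost_rank(chunk, n_rounds=cfg.n_rounds)
            survivors.extend(idx[ranked[:k]])
        if len(survivors) >= current.n_features:
            # single short chunk: final ranking pass
            ranked = logitboost_rank(current, n_rounds=cfg.n_rounds)
            return current.select(ranked[: cfg.final_k])
        survivors.sort()
        current = current.select(survivors)
    if current.n_features > cfg.final_k:
        ranked = logitboost_rank(current, n_rounds=cfg.n_rounds)
        current = current.select(ranked[: cfg.final_k])
    return current


# --------------------------------------------------------------- evaluation


def _median_heuristic_gamma(X: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    d2 = pdist(X, metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if (d2 > 0).any() else 1.0
    return 1.0 / med


def make_algorithms(seed: int = 0, X: np.ndarray | None = None) -> dict:
    """The seven classifier families, with documented default settings.

    ``X`` (the training matrix) sets the SVM gamma by the median heuristic
    and caps the KNN neighbour count at half the sample count so tiny
    cross-validation folds remain fittable.
    """
    gamma = _median_heuristic_gamma(X) if X is not None else "scale"
    knn_k = 5 if X is None else max(1, min(5, X.shape[0] // 2))
    return {
        "LogitBoost": LogitBoostClassifier(n_rounds=100),
        "Bag": BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=200,
            random_state=seed,
        ),
        "GentleBoost": GentleBoostClassifier(n_rounds=100),
        "Tree": DecisionTreeClassifier(random_state=seed),
        "SVM": SVC(kernel="rbf", gamma=gamma, random_state=seed),
        "NaiveBayes": GaussianNB(),
        "KNN": KNeighborsClassifier(n_neighbors=knn_k),
    }


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def compute_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, precision, F1 and accuracy from counts.

    Ratios with zero denominators are reported as NaN (masked).
    """
    if min(tp, fn, tn, fp) < 0 or tp + fn + tn + fp == 0:
        raise ValueError("counts must be non-negative with positive total")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    acc = (tp + tn) / (tp + fn + tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }


@dataclass
class AlgorithmReport:
    name: str
    cv_auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    fold_assignments: np.ndarray
    test_metrics: dict[str, float]
    confusion: tuple[int, int, int, int]  # TP, FN, TN, FP


@dataclass
class CVReport:
    algorithms: dict[str, AlgorithmReport]
    positive_class: object


def train_and_evaluate(
    fm_train: FeatureMatrix,
    fm_test: FeatureMatrix,
    algorithms: dict | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    positive_class=None,
) -> CVReport:
    """Stratified 10-fold CV ROC/AUC on train, held-out metrics on test.

    Out-of-fold decision scores are pooled into one ROC per algorithm; the
    final model is refit on the full training set and evaluated on the test
    set.  Deterministic given ``seed``.
    """
    X_tr, y_tr = fm_train.values, fm_train.labels
    X_te, y_te = fm_test.values, fm_test.labels
    classes = np.unique(y_tr)
    if len(classes) != 2:
        raise ValueError("training set must contain exactly two classes")
    if positive_class is None:
        positive_class = classes[1]
    if algorithms is None:
        algorithms = make_algorithms(seed=seed, X=X_tr)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = np.full(len(y_tr), -1, dtype=int)
    splits = list(skf.split(X_tr, y_tr))
    for k, (_, test_idx) in enumerate(splits):
        folds[test_idx] = k

    reports: dict[str, AlgorithmReport] = {}
    for name, proto in algorithms.items():
        oof = np.zeros(len(y_tr))
        for train_idx, test_idx in splits:
            model = clone(proto)
            model.fit(X_tr[train_idx], y_tr[train_idx])
            oof[test_idx] = _scores(model, X_tr[test_idx])
        fpr, tpr, _ = roc_curve(y_tr == positive_class, oof)
        cv_auc = float(auc(fpr, tpr))

        final = clone(proto)
        final.fit(X_tr, y_tr)
        pred = final.predict(X_te)
        pos = y_te == positive_class
        tp = int(np.sum(pos & (pred == positive_class)))
        fn = int(np.sum(pos & (pred != positive_class)))
        tn = int(np.sum(~pos & (pred != positive_class)))
        fp = int(np.sum(~pos & (pred == positive_class)))
        reports[name] = AlgorithmReport(
            name=name,
            cv_auc=cv_auc,
            roc_fpr=fpr,
            roc_tpr=tpr,
            fold_assignments=folds.copy(),
            test_metrics=compute_metrics(tp, fn, tn, fp),
            confusion=(tp, fn, tn, fp),
        )
    return CVReport(algorithms=reports, positive_class=positive_class)
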