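"""Fingerprint QSAR modeling grid for screening activity calls.

The modeling study: a 70/30 stratified split, per-feature selection on
the training data only (Fisher's exact test, per-feature AUC, or
ensemble importance ranks), class rebalancing (down/up-sampling, ROSE,
SMOTE), a five-family classifier grid (naive Bayes, one-hidden-layer
neural net, random forest, RBF SVM, gradient-boosted trees), repeated
stratified 3-fold cross-validation, and external validation with
AUC-ROC, balanced accuracy, and the Matthews correlation coefficient.

Feature selection and rebalancing always happen inside each training
fold, never on held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .exceptions import InvalidArgumentError, MissingDataError
from .synthetic import FingerprintDataset

__all__ = [
    "FeatureSelectionSpec",
    "EvalMetrics",
    "split_dataset",
    "fisher_feature_select",
    "fisher_pvalues",
    "auc_feature_select",
    "feature_aucs",
    "importance_feature_select",
    "rebalance",
    "train_classifier",
    "cross_validate_grid",
    "evaluate_external",
    "default_grid",
]

FAMILIES = ("naive_bayes", "neural_net_1hidden", "random_forest", "svm_rbf", "gradient_boosted_trees")
REBALANCERS = ("none", "down", "up", "rose", "smote")

FISHER_CUTOFFS = (0.01, 0.02, 0.03, 0.04, 0.05)
AUC_CUTOFFS = (0.52, 0.54, 0.56, 0.58, 0.60)
TOPK_CUTOFFS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class FeatureSelectionSpec:
    method: str  # fisher | auc | rf_importance | boost_importance
    cutoff: float  # p-value, AUC threshold, or top-k count

    def __post_init__(self):
        if self.method not in ("fisher", "auc", "rf_importance", "boost_importance"):
            raise InvalidArgumentError(f"unknown selection method {self.method!r}")


@dataclass
class EvalMetrics:
    auc_roc: float
    balanced_accuracy: float
    mcc: float
    auc_sd: float = 0.0
    ba_sd: float = 0.0
    mcc_sd: float = 0.0


def split_dataset(
    dataset: FingerprintDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[FingerprintDataset, FingerprintDataset]:
    """Disjoint, exhaustive train/test partition.

    The training partition has exactly ``round(n * train_fraction)``
    compounds; stratification (default) preserves the class imbalance in
    both partitions.
    """
    if not 0.0 < train_fraction < 1.0:
        raise InvalidArgumentError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset.labels)
    n_train = round(n * train_fraction)

    if stratify:
        train_idx: list[int] = []
        classes = np.unique(dataset.labels)
        targets = {}
        for c in classes:
            idx = np.flatnonzero(dataset.labels == c)
            targets[c] = idx[rng.permutation(len(idx))]
        # proportional per-class counts, remainder to the largest fraction
        quotas = {c: int(len(targets[c]) * train_fraction) for c in classes}
        while sum(quotas.values()) < n_train:
            c = max(
                classes,
                key=lambda c: len(targets[c]) * train_fraction - quotas[c],
            )
            quotas[c] += 1
        for c in classes:
            train_idx.extend(targets[c][: quotas[c]].tolist())
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
    else:
        perm = rng.permutation(n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:n_train]] = True

    def _subset(mask) -> FingerprintDataset:
        idx = np.flatnonzero(mask)
        return FingerprintDataset(
            matrix=dataset.matrix[idx],
            labels=dataset.labels[idx],
            compound_ids=[dataset.compound_ids[i] for i in idx],
            feature_ids=list(dataset.feature_ids),
            true_enriched=dataset.true_enriched,
        )

    return _subset(train_mask), _subset(~train_mask)


def fisher_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p-value per binary feature vs the label."""
    y = np.asarray(y).astype(bool)
    n_act, n_inact = int(y.sum()), int((~y).sum())
    if n_act == 0 or n_inact == 0:
        raise MissingDataError("both classes required for Fisher selection")
    pvals = np.ones(X.shape[1])
    cache: dict[tuple[int, int], float] = {}
    for j in range(X.shape[1]):
        a = int(X[y, j].sum())  # active & feature present
        c = int(X[~y, j].sum())  # inactive & feature present
        key = (a, c)
        if key not in cache:
            table = [[a, n_act - a], [c, n_inact - c]]
            cache[key] = float(stats.fisher_exact(table, alternative="two-sided")[1])
        pvals[j] = cache[key]
    return pvals


def fisher_feature_select(X: np.ndarray, y: np.ndarray, p_cutoff: float) -> np.ndarray:
    """Indices of features with two-sided Fisher p <= cutoff."""
    return np.flatnonzero(fisher_pvalues(X, y) <= p_cutoff)


def feature_aucs(X: np.ndarray, y: np.ndarray, fold_direction: bool = True) -> np.ndarray:
    """Per-feature AUC of the binary feature as a predictor of the label.

    For a binary feature the AUC has the closed form (TPR + TNR) / 2;
    with ``fold_direction`` the value is folded to max(AUC, 1 - AUC) so
    depletion-type features remain selectable.
    """
    y = np.asarray(y).astype(bool)
    n_act, n_inact = int(y.sum()), int((~y).sum())
    if n_act == 0 or n_inact == 0:
        raise MissingDataError("both classes required for AUC selection")
    tpr = X[y].mean(axis=0)
    fpr = X[~y].mean(axis=0)
    auc = (tpr + (1.0 - fpr)) / 2.0
    if fold_direction:
        auc = np.maximum(auc, 1.0 - auc)
    return auc


def auc_feature_select(
    X: np.ndarray, y: np.ndarray, auc_cutoff: float, fold_direction: bool = True
) -> np.ndarray:
    """Indices of features whose (direction-folded) AUC meets the cutoff."""
    return np.flatnonzero(feature_aucs(X, y, fold_direction) >= auc_cutoff)


def importance_feature_select(
    X: np.ndarray, y: np.ndarray, model_family: str, top_k: int, seed: int = 0
) -> np.ndarray:
    """Top-k features by ensemble importance (Gini or gain)."""
    if top_k > X.shape[1]:
        raise InvalidArgumentError("top_k cannot exceed the number of features")
    if model_family == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
        model.fit(X, y)
        importances = model.feature_importances_
    elif model_family == "gradient_boosted_trees":
        model = _xgb(seed)
        model.fit(X, y)
        importances = model.feature_importances_
    else:
        raise InvalidArgumentError(f"unknown importance family {model_family!r}")
    order = np.argsort(-importances, kind="stable")
    return np.sort(order[:top_k])


def _smote(X_min: np.ndarray, n_new: int, rng, k: int = 5) -> np.ndarray:
    """Minority oversampling by interpolation toward k nearest neighbors."""
    n_min = len(X_min)
    if n_min == 1:
        return np.repeat(X_min, n_new, axis=0)
    k_eff = min(k, n_min - 1)
    if k_eff < k:
        warnings.warn(f"SMOTE: minority class of {n_min}; using k={k_eff}", stacklevel=3)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)
    out = np.empty((n_new, X_min.shape[1]))
    for i in range(n_new):
        a = rng.integers(n_min)
        b = idx[a][1 + rng.integers(k_eff)]  # skip self at position 0
        u = rng.random()
        out[i] = X_min[a] + u * (X_min[b] - X_min[a])
    return out


def _rose_class(Xc: np.ndarray, n_new: int, rng) -> np.ndarray:
    """Smoothed bootstrap: resample rows and add Gaussian kernel noise."""
    n, d = Xc.shape
    sd = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
    h = sd * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    picks = rng.integers(n, size=n_new)
    return Xc[picks] + rng.normal(0.0, 1.0, size=(n_new, d)) * h


def rebalance(
    X: np.ndarray, y: np.ndarray, method: str = "none", seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a binary training set.

    ``down``/``up`` sample to the minority/majority count; ``smote``
    synthesizes minority examples by nearest-neighbor interpolation
    (fractional coordinates are kept); ``rose`` draws a balanced smoothed
    bootstrap of the original size.
    """
    if method == "none":
        return X, y
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise MissingDataError("rebalancing requires both classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    X_min, X_maj = X[y == minority], X[y == majority]

    if method == "down":
        picks = rng.permutation(len(X_maj))[: len(X_min)]
        Xb = np.vstack([X_min, X_maj[picks]])
        yb = np.concatenate([np.full(len(X_min), minority), np.full(len(X_min), majority)])
    elif method == "up":
        picks = rng.integers(len(X_min), size=len(X_maj))
        Xb = np.vstack([X_min[picks], X_maj])
        yb = np.concatenate([np.full(len(X_maj), minority), np.full(len(X_maj), majority)])
    elif method == "smote":
        n_new = len(X_maj) - len(X_min)
        X_new = _smote(X_min, n_new, rng, k=k_neighbors)
        Xb = np.vstack([X_min, X_new, X_maj])
        yb = np.concatenate(
            [np.full(len(X_min) + n_new, minority), np.full(len(X_maj), majority)]
        )
    elif method == "rose":
        half = len(y) // 2
        Xb = np.vstack([_rose_class(X_min, half, rng), _rose_class(X_maj, len(y) - half, rng)])
        yb = np.concatenate([np.full(half, minority), np.full(len(y) - half, majority)])
    else:
        raise InvalidArgumentError(f"unknown rebalancing method {method!r}")
    perm = rng.permutation(len(yb))
    return Xb[perm], yb[perm]


def _xgb(seed: int) -> XGBClassifier:
    # stated constants: learning rate 0.01, max depth 3, column subsample 0.5
    return XGBClassifier(
        n_estimators=100,
        learning_rate=0.01,
        max_depth=3,
        colsample_bytree=0.5,
        random_state=seed,
        verbosity=0,
        eval_metric="logloss",
    )


def train_classifier(X: np.ndarray, y: np.ndarray, family: str, seed: int = 0):
    """Fit one classifier family with documented defaults."""
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("non-finite values in the feature matrix")
    if family == "naive_bayes":
        model = BernoulliNB(alpha=1.0, binarize=0.5)  # Laplace smoothing
    elif family == "neural_net_1hidden":
        hidden = max(2, round(np.sqrt(X.shape[1])))
        model = MLPClassifier(
            hidden_layer_sizes=(hidden,), max_iter=500, random_state=seed
        )
    elif family == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif family == "svm_rbf":
        model = SVC(kernel="rbf", probability=False, random_state=seed)
    elif family == "gradient_boosted_trees":
        model = _xgb(seed)
    else:
        raise InvalidArgumentError(f"unknown classifier family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings on tiny folds
        model.fit(X, y)
    return model


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _metrics(y_true: np.ndarray, score: np.ndarray, threshold: float) -> tuple[float, float, float]:
    if len(np.unique(y_true)) < 2:
        raise MissingDataError("AUC undefined: a class is missing from the evaluation set")
    pred = (score >= threshold).astype(int)
    return (
        float(roc_auc_score(y_true, score)),
        float(balanced_accuracy_score(y_true, pred)),
        float(matthews_corrcoef(y_true, pred)),
    )


def _select(X, y, spec: FeatureSelectionSpec, seed: int) -> np.ndarray:
    if spec.method == "fisher":
        sel = fisher_feature_select(X, y, spec.cutoff)
        if sel.size == 0:  # degenerate fold: keep the single best feature
            sel = np.array([int(np.argmin(fisher_pvalues(X, y)))])
        return sel
    if spec.method == "auc":
        sel = auc_feature_select(X, y, spec.cutoff)
        if sel.size == 0:
            sel = np.array([int(np.argmax(feature_aucs(X, y)))])
        return sel
    family = "random_forest" if spec.method == "rf_importance" else "gradient_boosted_trees"
    return importance_feature_select(X, y, family, int(spec.cutoff), seed=seed)


def cross_validate_grid(
    train: FingerprintDataset,
    specs: list[FeatureSelectionSpec],
    rebalancers: list[str],
    families: list[str],
    n_folds: int = 3,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV over the full modeling grid.

    Feature selection and rebalancing run inside each training fold only.
    Returns one row per (selection spec, rebalancer, family) with mean and
    sd of AUC-ROC, balanced accuracy, and MCC across repeats (each repeat
    averages its folds).
    """
    if not specs or not rebalancers or not families:
        raise InvalidArgumentError("grid must be non-empty")
    X, y = train.matrix.astype(float), train.labels
    results = {
        (spec, rb, fam): [] for spec in specs for rb in rebalancers for fam in families
    }
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        fold_metrics = {key: [] for key in results}
        for tr_idx, te_idx in skf.split(X, y):
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_te, y_te = X[te_idx], y[te_idx]
            for spec in specs:
                sel = _select(X_tr, y_tr, spec, seed + rep)
                for rb in rebalancers:
                    X_rb, y_rb = rebalance(X_tr[:, sel], y_tr, rb, seed=seed + rep)
                    for fam in families:
                        model = train_classifier(X_rb, y_rb, fam, seed=seed + rep)
                        score = _scores(model, X_te[:, sel])
                        thr = 0.5 if hasattr(model, "predict_proba") else 0.0
                        fold_metrics[(spec, rb, fam)].append(_metrics(y_te, score, thr))
        for key, vals in fold_metrics.items():
            results[key].append(np.mean(vals, axis=0))

    rows = []
    for (spec, rb, fam), reps in results.items():
        arr = np.asarray(reps)
        mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=0)
        rows.append(
            {
                "selection": spec.method,
                "cutoff": spec.cutoff,
                "rebalance": rb,
                "family": fam,
                "auc_mean": mean[0],
                "auc_sd": sd[0],
                "ba_mean": mean[1],
                "ba_sd": sd[1],
                "mcc_mean": mean[2],
                "mcc_sd": sd[2],
            }
        )
    return pd.DataFrame(rows)


def evaluate_external(
    model, test: FingerprintDataset, selected_features: np.ndarray | None = None
) -> EvalMetrics:
    """AUC-ROC, balanced accuracy, and MCC on an untouched holdout."""
    X = test.matrix.astype(float)
    if selected_features is not None:
        X = X[:, selected_features]
    score = _scores(model, X)
    thr = 0.5 if hasattr(model, "predict_proba") else 0.0
    auc, ba, mcc = _metrics(test.labels, score, thr)
    return EvalMetrics(auc, ba, mcc)


def default_grid() -> list[FeatureSelectionSpec]:
    """The full published selection grid: 20 specs across four methods."""
    specs = [FeatureSelectionSpec("fisher", c) for c in FISHER_CUTOFFS]
    specs += [FeatureSelectionSpec("auc", c) for c in AUC_CUTOFFS]
    specs += [FeatureSelectionSpec("rf_importance", k) for k in TOPK_CUTOFFS]
    specs += [FeatureSelectionSpec("boost_importance", k) for k in TOPK_CUTOFFS]
    return specs
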