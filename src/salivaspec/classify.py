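"""Classifiers for the screening pipeline.

The workhorse is the Mahalanobis-distance discriminant pair:

* linear (LDA): one pooled covariance, so class boundaries are hyperplanes;
* quadratic (QDA): one covariance per class.  The quadratic discriminant
  value is ``d_c(x) = (x - mu_c)' Sigma_c^-1 (x - mu_c) + ln|Sigma_c|
  - 2 ln pi_c`` and a sample is assigned to the class minimising it.

QDA is the method of interest here: the cancer class is both much smaller
and much *tighter* (lower variance) than the control class, and a per-class
covariance lets the boundary wrap that tight cluster.  Priors default to
equal — with a ~30:1 imbalance, proportional priors would swamp
sensitivity.  PLS-DA, SVM and KNN are comparison methods, built on
scikit-learn estimators behind the same output contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .chemometrics import PLSModel, _stratified_folds, fit_pls, pls_scores

__all__ = [
    "DiscriminantModel",
    "ClassifierOutput",
    "fit_discriminant",
    "predict_discriminant",
    "PLSDAModel",
    "fit_plsda",
    "predict_plsda",
    "KNNModel",
    "fit_knn",
    "predict_knn",
    "SVMModel",
    "fit_svm",
    "predict_svm",
    "cross_validate",
]

POSITIVE, CONTROL = "positive", "control"


@dataclass
class ClassifierOutput:
    predicted: np.ndarray  # label per row
    decision_score: np.ndarray  # higher => more positive-class-like
    discriminants: dict | None = None  # per-class discriminant values


# ----------------------------------------------------------------------
# LDA / QDA


@dataclass
class DiscriminantModel:
    kind: str  # linear | quadratic
    class_labels: list
    means: dict
    covariances: dict  # per class (quadratic) or {"pooled": ...} (linear)
    inverses: dict
    logdets: dict
    priors: dict
    pos_label: object


def _regularise(cov: np.ndarray) -> np.ndarray:
    """Add an escalating ridge until the covariance is positive definite.

    Starts at ``1e-8 * trace/dim`` and multiplies by 10 until a Cholesky
    factorisation succeeds; needed because e.g. a 22-sample class in 8 PCs
    has a near-singular covariance.
    """
    dim = cov.shape[0]
    eps = 1e-8 * max(np.trace(cov) / dim, np.finfo(float).tiny)
    for _ in range(60):
        try:
            np.linalg.cholesky(cov + eps * np.eye(dim))
            return cov + eps * np.eye(dim)
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise np.linalg.LinAlgError("covariance could not be regularised")


def fit_discriminant(
    X: np.ndarray,
    labels: np.ndarray,
    kind: str = "quadratic",
    priors: str = "equal",
    pos_label=POSITIVE,
) -> DiscriminantModel:
    """Fit class means and (pooled or per-class) covariances.

    ``priors`` is ``equal`` (default; screening should not let a 30:1
    imbalance silence the minority class) or ``proportional``.
    """
    if kind not in ("linear", "quadratic"):
        raise ValueError(f"kind must be linear or quadratic, not {kind!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(labels):  # 1-D feature vector
        X = X.T
    labels = np.asarray(labels)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError("binary discriminant needs exactly two classes")
    means, covs, ns = {}, {}, {}
    for c in classes:
        rows = X[labels == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[c] = rows.mean(axis=0)
        covs[c] = np.cov(rows, rowvar=False).reshape(X.shape[1], X.shape[1])
        ns[c] = rows.shape[0]

    if priors == "equal":
        pri = {c: 1.0 / len(classes) for c in classes}
    elif priors == "proportional":
        n = sum(ns.values())
        pri = {c: ns[c] / n for c in classes}
    else:
        raise ValueError(f"priors must be 'equal' or 'proportional', not {priors!r}")

    inverses, logdets = {}, {}
    if kind == "linear":
        n = sum(ns.values())
        pooled = sum((ns[c] - 1) * covs[c] for c in classes) / (n - len(classes))
        pooled = _regularise(pooled)
        covs = {"pooled": pooled}
        inv = np.linalg.inv(pooled)
        for c in classes:
            inverses[c] = inv
            logdets[c] = 0.0  # common log-determinant cancels in LDA
    else:
        for c in classes:
            covs[c] = _regularise(covs[c])
            inverses[c] = np.linalg.inv(covs[c])
            logdets[c] = float(np.linalg.slogdet(covs[c])[1])

    return DiscriminantModel(
        kind=kind, class_labels=classes, means=means, covariances=covs,
        inverses=inverses, logdets=logdets, priors=pri, pos_label=pos_label,
    )


def _discriminant_values(model: DiscriminantModel, X: np.ndarray) -> dict:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dim = next(iter(model.means.values())).size
    if X.shape[1] != dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension {dim}")
    vals = {}
    for c in model.class_labels:
        diff = X - model.means[c]
        maha = np.einsum("ij,jk,ik->i", diff, model.inverses[c], diff)
        vals[c] = maha + model.logdets[c] - 2.0 * np.log(model.priors[c])
    return vals


def predict_discriminant(model: DiscriminantModel, X: np.ndarray) -> ClassifierOutput:
    """Assign each row to the class with the smaller discriminant value.

    Exact ties go to the non-positive class: a screening call-back should
    only be triggered by a strictly better positive fit.  The decision
    score is ``d_other(x) - d_positive(x)`` (higher = more cancer-like),
    which makes ROC/AUC computable from any fitted model.
    """
    vals = _discriminant_values(model, X)
    pos = model.pos_label
    other = next(c for c in model.class_labels if c != pos)
    score = vals[other] - vals[pos]
    predicted = np.where(score > 0, pos, other).astype(object)
    return ClassifierOutput(predicted=predicted, decision_score=score, discriminants=vals)


# ----------------------------------------------------------------------
# PLS-DA


@dataclass
class PLSDAModel:
    pls: PLSModel
    lda: DiscriminantModel
    a: int


def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    a: int | None = None,
    folds: int = 10,
    seed: int = 0,
    pos_label=POSITIVE,
) -> PLSDAModel:
    """PLS latent variables against class membership, then a linear
    discriminant on the LV scores.  ``a`` is picked by stratified CV
    accuracy when not given."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if a is None:
        amax = min(10, X.shape[0] - 2, X.shape[1])
        grid = [{"a": v} for v in range(1, amax + 1)]
        best = cross_validate(
            lambda X, y, a: fit_plsda(X, y, a=a, pos_label=pos_label),
            lambda m, X: predict_plsda(m, X),
            grid, X, labels, folds=folds, seed=seed,
        )
        a = best["best_params"]["a"]
    pls = fit_pls(X, labels == pos_label, a)
    lda = fit_discriminant(pls.x_scores, labels, kind="linear", pos_label=pos_label)
    return PLSDAModel(pls=pls, lda=lda, a=a)


def predict_plsda(model: PLSDAModel, X: np.ndarray) -> ClassifierOutput:
    return predict_discriminant(model.lda, pls_scores(model.pls, X))


# ----------------------------------------------------------------------
# KNN


@dataclass
class KNNModel:
    k: int
    sk: KNeighborsClassifier
    pos_label: object
    n_train: int


def fit_knn(
    X: np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
    folds: int = 10,
    seed: int = 0,
    pos_label=POSITIVE,
) -> KNNModel:
    """Euclidean majority-vote classifier; odd ``k`` grid 1..15 by CV when unset."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if k is None:
        grid = [{"k": v} for v in range(1, 16, 2) if v <= X.shape[0] - 1]
        best = cross_validate(
            lambda X, y, k: fit_knn(X, y, k=k, pos_label=pos_label),
            lambda m, X: predict_knn(m, X),
            grid, X, labels, folds=folds, seed=seed,
        )
        k = best["best_params"]["k"]
    if not (1 <= k <= X.shape[0]):
        raise ValueError(f"k={k} exceeds the training size {X.shape[0]}")
    sk = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    sk.fit(X, labels)
    return KNNModel(k=k, sk=sk, pos_label=pos_label, n_train=X.shape[0])


def predict_knn(model: KNNModel, X: np.ndarray) -> ClassifierOutput:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    predicted = model.sk.predict(X).astype(object)
    classes = list(model.sk.classes_)
    proba = model.sk.predict_proba(X)
    if model.pos_label in classes:
        score = proba[:, classes.index(model.pos_label)]
    else:
        score = np.zeros(X.shape[0])
    return ClassifierOutput(predicted=predicted, decision_score=score)


# ----------------------------------------------------------------------
# SVM


_DEFAULT_COSTS = [10.0**e for e in range(-2, 4)]


@dataclass
class SVMModel:
    kernel: str
    sk: SVC
    pos_label: object
    params: dict


def _svc(kernel: str, cost: float, gamma: float | None) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=cost)
    if kernel == "poly2":
        return SVC(kernel="poly", degree=2, C=cost, gamma="scale", coef0=1.0)
    if kernel == "rbf":
        return SVC(kernel="rbf", C=cost, gamma=gamma if gamma else "scale")
    raise ValueError(f"unknown kernel {kernel!r}; use linear, poly2 or rbf")


def fit_svm(
    X: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    params: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    pos_label=POSITIVE,
) -> SVMModel:
    """Maximum-margin classifier; cost (and RBF width) tuned by stratified CV.

    Default grids: cost 10^-2..10^3; RBF gamma from the median pairwise
    distance heuristic scaled by {0.25, 0.5, 1, 2, 4}.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if params is None:
        costs = _DEFAULT_COSTS
        if kernel == "rbf":
            med = np.median(cdist(X, X)[np.triu_indices(X.shape[0], 1)])
            med = med if med > 0 else 1.0
            gammas = [1.0 / (2.0 * (s * med) ** 2) for s in (0.25, 0.5, 1.0, 2.0, 4.0)]
        else:
            gammas = [None]
        grid = [{"cost": c, "gamma": g} for c, g in product(costs, gammas)]
        best = cross_validate(
            lambda X, y, cost, gamma: fit_svm(
                X, y, kernel=kernel, params={"cost": cost, "gamma": gamma},
                pos_label=pos_label,
            ),
            lambda m, X: predict_svm(m, X),
            grid, X, labels, folds=folds, seed=seed,
        )
        params = best["best_params"]
    sk = _svc(kernel, params.get("cost", 1.0), params.get("gamma"))
    sk.fit(X, labels)
    return SVMModel(kernel=kernel, sk=sk, pos_label=pos_label, params=dict(params))


def predict_svm(model: SVMModel, X: np.ndarray) -> ClassifierOutput:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    predicted = model.sk.predict(X).astype(object)
    score = model.sk.decision_function(X)
    if list(model.sk.classes_)[-1] != model.pos_label:
        score = -score
    return ClassifierOutput(predicted=predicted, decision_score=score)


# ----------------------------------------------------------------------
# generic stratified cross-validation


def cross_validate(
    fit,
    predict,
    grid: list[dict],
    X: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Grid search by stratified k-fold accuracy; deterministic given seed.

    ``fit(X, y, **params)`` builds a model, ``predict(model, X)`` returns a
    :class:`ClassifierOutput`.  Returns the best parameter set (ties break
    toward the earlier grid entry) plus per-point mean/SD accuracy.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    folds = min(folds, len(labels))
    rng = np.random.default_rng(seed)
    fold_ids = _stratified_folds(labels, folds, rng)
    rows = []
    for params in grid:
        accs = []
        for f in range(folds):
            tr, te = fold_ids != f, fold_ids == f
            if not te.any():
                continue
            model = fit(X[tr], labels[tr], **params)
            pred = predict(model, X[te]).predicted
            accs.append(float(np.mean(pred == labels[te])))
        accs = np.asarray(accs)
        rows.append(
            {"params": params, "mean_accuracy": accs.mean(),
             "sd_accuracy": accs.std(ddof=1) if folds > 1 else 0.0}
        )
    best = max(rows, key=lambda r: r["mean_accuracy"])
    return {"best_params": best["params"], "cv_table": rows,
            "best_accuracy": best["mean_accuracy"]}
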