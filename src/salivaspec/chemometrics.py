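"""Decomposition, outlier rejection, representative splitting and variable
selection: PCA via SVD, Hotelling T2 vs Q residuals, the Kennard-Stone
splitter, PLS latent variables, and genetic-algorithm wavenumber selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression

from .dataset import SpectralDataset

__all__ = [
    "PCAModel",
    "fit_pca",
    "project",
    "select_k",
    "OutlierReport",
    "hotelling_q_outliers",
    "SplitResult",
    "kennard_stone_split",
    "random_split",
    "PLSModel",
    "fit_pls",
    "pls_scores",
    "GAConfig",
    "GAResult",
    "ga_select",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ----------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Principal components of a centred matrix, via SVD.

    ``loadings`` (n_points x K) are orthonormal; ``scores = X @ loadings``;
    ``eigenvalues`` are the score-column variances (ddof=1);
    ``explained_pct`` their percentages of total variance.
    ``all_eigenvalues`` keeps the full eigen-spectrum — the residual tail is
    needed for the Q-statistic control limit.
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    all_eigenvalues: np.ndarray
    n_train: int

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Fit a rank-``k`` PCA to the already-centred matrix ``X``."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    all_eigenvalues = s**2 / (n - 1)
    total = all_eigenvalues.sum()
    loadings = vt[:k].T
    scores = X @ loadings
    eigenvalues = all_eigenvalues[:k]
    explained_pct = 100.0 * eigenvalues / total if total > 0 else np.zeros(k)
    return PCAModel(loadings, scores, eigenvalues, explained_pct, all_eigenvalues, n)


def project(model: PCAModel, rows: np.ndarray) -> np.ndarray:
    """Project new rows (centred with the training mean) onto the loadings."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != model.loadings.shape[0]:
        raise ValueError("row length does not match the fitted axis")
    return rows @ model.loadings


def select_k(
    X: np.ndarray,
    labels: np.ndarray | None = None,
    strategy: str = "cv_accuracy",
    limit: int = 15,
    threshold: float = 0.90,
    folds: int = 10,
    seed: int = 0,
    kind: str = "quadratic",
) -> int:
    """Choose the retained PC count ``K``.

    ``explained_variance_threshold``: smallest K whose cumulative explained
    variance reaches ``threshold``.  ``cv_accuracy``: smallest K whose
    stratified ``folds``-fold CV accuracy (discriminant of the given kind on
    the leading K score columns, PCA refit per training fold) is within one
    standard error of the best K.  Deterministic given ``seed``.
    """
    from .classify import fit_discriminant, predict_discriminant  # cycle guard

    if limit < 1:
        raise ValueError("limit must be >= 1")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    # effective numerical rank caps the K grid
    svals = np.linalg.svd(X, compute_uv=False)
    rank = int(np.sum(svals > svals[0] * 1e-10)) if svals.size and svals[0] > 0 else 1
    kmax = max(1, min(limit, rank, n - 1, p))

    if strategy == "explained_variance_threshold":
        ev = svals**2
        frac = np.cumsum(ev) / ev.sum()
        return int(np.searchsorted(frac, threshold - 1e-12) + 1) if frac[0] < threshold else 1

    if strategy != "cv_accuracy":
        raise ValueError(f"unknown strategy {strategy!r}")
    if labels is None:
        raise ValueError("cv_accuracy strategy needs class labels")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = min(folds, int(min(np.unique(labels, return_counts=True)[1])))
    fold_ids = _stratified_folds(labels, folds, rng)
    acc = np.zeros((folds, kmax))
    for f in range(folds):
        tr, te = fold_ids != f, fold_ids == f
        mean = X[tr].mean(axis=0)
        sub = fit_pca(X[tr] - mean, min(kmax, tr.sum() - 1, p))
        str_full = (X[tr] - mean) @ sub.loadings
        ste_full = (X[te] - mean) @ sub.loadings
        for k in range(1, kmax + 1):
            kk = min(k, sub.k)
            model = fit_discriminant(str_full[:, :kk], labels[tr], kind=kind)
            pred = predict_discriminant(model, ste_full[:, :kk]).predicted
            acc[f, k - 1] = np.mean(pred == labels[te])
    mean_acc = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmax(mean_acc))
    cutoff = mean_acc[best] - se[best]
    return int(np.nonzero(mean_acc >= cutoff - 1e-12)[0][0] + 1)


def _stratified_folds(labels: np.ndarray, folds: int, rng) -> np.ndarray:
    """Assign each row to one of ``folds`` class-stratified folds."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    out = np.empty(len(labels), dtype=int)
    start = 0  # rotate the fold offset across classes so no fold stays empty
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        perm = rng.permutation(len(idx))
        out[idx[perm]] = (np.arange(len(idx)) + start) % folds
        start += len(idx)
    return out


# ----------------------------------------------------------------------
# Hotelling T2 vs Q residuals


@dataclass
class OutlierReport:
    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    alpha: float
    flags: np.ndarray


def hotelling_q_outliers(
    model: PCAModel, X: np.ndarray, alpha: float = 0.95
) -> OutlierReport:
    """Joint Hotelling T2 / Q-residual outlier test on centred rows ``X``.

    ``t2_i = sum_k score_ik^2 / eigenvalue_k`` over the K retained PCs, with
    control limit ``K (n-1)/(n-K) * F_alpha(K, n-K)``; ``q_i`` is the
    squared residual norm off the PC subspace with the Jackson-Mudholkar
    limit built from the residual eigenvalue tail.  A row is flagged only
    when it exceeds *both* limits — the conservative joint-plot criterion; a
    row extreme in a single statistic is retained.
    """
    if np.any(model.eigenvalues <= 0):
        raise ValueError("non-positive eigenvalue in the PCA model")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = project(model, X)
    t2 = np.sum(scores**2 / model.eigenvalues, axis=1)
    resid = X - scores @ model.loadings.T
    q = np.sum(resid**2, axis=1)

    n, k = model.n_train, model.k
    if n <= k:
        raise ValueError("T2 limit undefined: n_train <= K")
    t2_limit = k * (n - 1) / (n - k) * stats.f.ppf(alpha, k, n - k)

    tail = model.all_eigenvalues[k:]
    tail = tail[tail > 0]
    if tail.size == 0:
        q_limit = 0.0
    else:
        th1, th2, th3 = (np.sum(tail**i) for i in (1, 2, 3))
        h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
        if h0 <= 0:
            h0 = 1e-4
        c = stats.norm.ppf(alpha)
        q_limit = th1 * (
            c * np.sqrt(2.0 * th2 * h0**2) / th1
            + 1.0
            + th2 * h0 * (h0 - 1.0) / th1**2
        ) ** (1.0 / h0)
    flags = (t2 > t2_limit) & (q > q_limit)
    return OutlierReport(t2, q, float(t2_limit), float(q_limit), alpha, flags)


# ----------------------------------------------------------------------
# Kennard-Stone split


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    fraction: float


def kennard_stone_split(
    ds: SpectralDataset,
    fraction: float = 0.70,
    per_class: bool = True,
    distance: str = "euclidean",
) -> SplitResult:
    """Deterministic representative train/test split by max-min distance.

    Within each class (or over the whole cohort when ``per_class=False``):
    start from the two mutually most distant samples, then repeatedly add
    the sample whose minimum distance to the selected set is largest, until
    ``round(fraction * class size)`` samples are selected; those form the
    training set.  Ties break toward the smallest sample id, which also
    makes the split invariant to input row order.
    """
    if distance != "euclidean":
        raise ValueError(f"unsupported distance {distance!r}")
    if ds.meta["sample_id"].duplicated().any():
        raise ValueError("split operates on one row per sample; average replicates first")
    train_ids: list = []
    test_ids: list = []
    groups = (
        ds.meta.groupby("label", sort=True).groups.items()
        if per_class
        else [("all", ds.meta.index)]
    )
    for _, idx in groups:
        idx = np.asarray(list(idx))
        ids = ds.meta["sample_id"].iloc[idx].to_numpy()
        order = np.argsort(ids, kind="stable")  # tie-break: smallest id first
        idx, ids = idx[order], ids[order]
        n = len(idx)
        if n < 2:
            raise ValueError(f"class with {n} sample(s); need >= 2 to split")
        n_train = _round_half_up(fraction * n)
        n_train = min(max(n_train, 2), n)
        sel = _kennard_stone(ds.intensities[idx], n_train)
        chosen = np.zeros(n, dtype=bool)
        chosen[sel] = True
        train_ids.extend(ids[chosen])
        test_ids.extend(ids[~chosen])
    return SplitResult(sorted(train_ids), sorted(test_ids), fraction)


def _kennard_stone(X: np.ndarray, n_select: int) -> list[int]:
    d = cdist(X, X)
    # farthest pair; np.argmax returns the first (smallest-id) maximiser
    start = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(start), max(start)]
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    min_d[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf
    return selected


def random_split(
    ds: SpectralDataset, fraction: float = 0.70, seed: int = 0, per_class: bool = True
) -> SplitResult:
    """Plain seeded per-class random split (test-harness baseline)."""
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    groups = (
        ds.meta.groupby("label", sort=True).groups.items()
        if per_class
        else [("all", ds.meta.index)]
    )
    for _, idx in groups:
        ids = np.sort(ds.meta["sample_id"].iloc[list(idx)].to_numpy())
        n_train = _round_half_up(fraction * len(ids))
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return SplitResult(sorted(train_ids), sorted(test_ids), fraction)


# ----------------------------------------------------------------------
# PLS


@dataclass
class PLSModel:
    """PLS latent-variable model against dummy-coded class membership."""

    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    a: int
    _sk: PLSRegression

    @property
    def n_components(self) -> int:
        return self.a


def fit_pls(X: np.ndarray, y: np.ndarray, a: int) -> PLSModel:
    """Fit ``a`` latent variables maximising covariance between X and y.

    ``y`` may be a numeric dummy vector or a label vector; labels are coded
    positive=1, other=0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind not in "fiub":
        y = (y == "positive").astype(float)
    y = y.astype(float)
    n, p = X.shape
    if not (1 <= a <= min(n - 1, p)):
        raise ValueError(f"A={a} out of range for a {n}x{p} matrix")
    sk = PLSRegression(n_components=a, scale=False)
    sk.fit(X, y)
    return PLSModel(
        x_weights=sk.x_weights_,
        x_loadings=sk.x_loadings_,
        x_scores=sk.x_scores_,
        y_loadings=sk.y_loadings_,
        x_mean=X.mean(axis=0),
        a=a,
        _sk=sk,
    )


def pls_scores(model: PLSModel, rows: np.ndarray) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return model._sk.transform(rows)


# ----------------------------------------------------------------------
# Genetic-algorithm variable selection


@dataclass
class GAConfig:
    """GA over binary wavenumber masks; defaults follow the study's run
    (100 generations of 200 chromosomes, 60% crossover, 1% mutation)."""

    generations: int = 100
    population: int = 200
    crossover_prob: float = 0.60
    mutation_prob: float = 0.01
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass
class GAResult:
    selected: np.ndarray  # sorted variable indices of the best mask
    mask: np.ndarray  # boolean over variables
    fitness: float  # CV misclassification of the best mask
    trajectory: list[float]  # best fitness per generation (non-increasing)


def ga_select(X: np.ndarray, labels: np.ndarray, config: GAConfig = GAConfig()) -> GAResult:
    """Evolve a wavenumber mask minimising inner-LDA CV misclassification.

    Tournament selection (size 2), single-point crossover, per-bit flip
    mutation, elitism of one.  Fitness is the stratified ``cv_folds``-fold
    CV misclassification rate of a linear discriminant restricted to the
    masked variables; folds are fixed once per run so chromosome fitnesses
    are comparable across generations.  Deterministic given the seed.
    """
    from .classify import fit_discriminant, predict_discriminant

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    folds = min(config.cv_folds, int(min(np.unique(labels, return_counts=True)[1])))
    fold_ids = _stratified_folds(labels, folds, rng)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key in cache:
            return cache[key]
        Xm = X[:, mask]
        errs = 0
        for f in range(folds):
            tr, te = fold_ids != f, fold_ids == f
            model = fit_discriminant(Xm[tr], labels[tr], kind="linear")
            pred = predict_discriminant(model, Xm[te]).predicted
            errs += int(np.sum(pred != labels[te]))
        rate = errs / n
        cache[key] = rate
        return rate

    pop = rng.random((config.population, p)) < 0.5
    for i in range(config.population):  # no empty chromosomes
        if not pop[i].any():
            pop[i, rng.integers(p)] = True
    fits = np.array([fitness(m) for m in pop])
    trajectory = [float(fits.min())]

    for _ in range(config.generations):
        elite = pop[int(np.argmin(fits))].copy()
        children = np.empty_like(pop)
        for i in range(0, config.population, 2):
            a = _tournament(fits, rng)
            b = _tournament(fits, rng)
            c1, c2 = pop[a].copy(), pop[b].copy()
            if rng.random() < config.crossover_prob and p > 1:
                cut = int(rng.integers(1, p))
                c1[cut:], c2[cut:] = pop[b][cut:], pop[a][cut:]
            children[i] = c1
            if i + 1 < config.population:
                children[i + 1] = c2
        if config.mutation_prob > 0:
            flips = rng.random(children.shape) < config.mutation_prob
            children ^= flips
        for i in range(config.population):
            if not children[i].any():
                children[i, rng.integers(p)] = True
        children[0] = elite  # elitism of 1
        pop = children
        fits = np.array([fitness(m) for m in pop])
        trajectory.append(float(fits.min()))

    best = int(np.argmin(fits))
    mask = pop[best]
    return GAResult(
        selected=np.nonzero(mask)[0],
        mask=mask,
        fitness=float(fits[best]),
        trajectory=trajectory,
    )


def _tournament(fits: np.ndarray, rng) -> int:
    i, j = rng.integers(len(fits), size=2)
    return int(i if fits[i] <= fits[j] else j)
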