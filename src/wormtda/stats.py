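"""Statistical battery over average-landscape feature vectors.

Classical MDS, functional PCA of landscapes, per-class coordinate standard
deviations, two-group label-permutation tests, multiclass SVM and SVR under
repeated stratified cross-validation, and the two simple baselines (mean
frame-to-frame speed; per-coordinate posture standard deviation).

Conventions, fixed for reproducibility where the original analysis relied on
an R implementation's defaults: RBF kernel with median-heuristic bandwidth
(``gamma = 1 / (2 * median^2)`` over pairwise feature distances), cost 10,
stratified folds, and explicit seeds for every stochastic step.  The
permutation p-value is the plain proportion of permuted statistics at least
as large as the observed one (resolution floor ``1/n_perm``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import SVC, SVR

from .series import TimeSeries


@dataclass
class LabeledFeatures:
    """Sample-by-feature matrix with class labels and optional numeric targets."""

    vectors: np.ndarray
    labels: list[str]
    numeric_targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = list(self.labels)
        if self.vectors.ndim != 2 or len(self.vectors) != len(self.labels):
            raise ValueError("vectors must be (n_samples, n_features) matching labels")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("features contain missing values")
        if self.numeric_targets is not None:
            self.numeric_targets = np.asarray(self.numeric_targets, dtype=float)
            if len(self.numeric_targets) != len(self.labels):
                raise ValueError("numeric_targets length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def classes(self) -> list[str]:
        seen = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)


def classical_mds(D: np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix and embeds into the top
    ``dim`` eigendirections; exact for Euclidean-realizable distances.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)


def landscape_pca(F: LabeledFeatures, k: int):
    """PCA of the feature matrix.

    Returns ``(components, projections, cumulative_variance)``; components
    are rows in feature space (reshapeable to (depth, grid) for functional
    plots).  ``k`` beyond the matrix rank is truncated with a warning.
    """
    X = F.vectors
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if k > rank:
        import warnings

        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = max(rank, 1)
    var = s**2
    cumvar = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
    components = Vt[:k]
    projections = Xc @ components.T
    return components, projections, cumvar[:k]


def coordinatewise_std(F: LabeledFeatures) -> dict[str, np.ndarray]:
    """Per-class, per-coordinate sample standard deviation (ddof=1)."""
    out = {}
    for cls in F.classes():
        rows = F.vectors[[lab == cls for lab in F.labels]]
        if len(rows) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        out[cls] = rows.std(axis=0, ddof=1)
    return out


def permutation_test(
    groupA: np.ndarray,
    groupB: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-group permutation test on the distance between group means.

    The statistic is the Euclidean distance between the two group mean
    vectors; labels are permuted uniformly ``n_perm`` times and the p-value
    is the proportion of permuted statistics >= the observed one.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.vstack([A, B])
    nA = len(A)
    observed = float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(X))
        stat = float(
            np.linalg.norm(X[perm[:nA]].mean(axis=0) - X[perm[nA:]].mean(axis=0))
        )
        if stat >= observed:
            count += 1
    return count / n_perm


def pairwise_permutation_tests(
    F: LabeledFeatures, n_perm: int = 10000, seed: int = 0
) -> dict[tuple[str, str], float]:
    """Permutation test for every unordered class pair."""
    classes = F.classes()
    out = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            A = F.vectors[[lab == a for lab in F.labels]]
            B = F.vectors[[lab == b for lab in F.labels]]
            out[(a, b)] = permutation_test(A, B, n_perm=n_perm, seed=seed)
    return out


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


def svm_classify(
    F: LabeledFeatures,
    folds: int = 10,
    cost: float = 10.0,
    repeats: int = 20,
    seed: int = 0,
):
    """Multiclass SVM accuracy under repeated stratified k-fold CV.

    RBF kernel with median-heuristic bandwidth, one-vs-one multiclass, cost
    ``C``.  Returns ``(mean accuracy over repeats, confusion matrix from the
    first repeat)``; confusion rows are true classes, columns predictions,
    ordered as ``F.classes()``.
    """
    X, y = F.vectors, np.asarray(F.labels)
    if len(X) < folds:
        raise ValueError("fewer samples than folds")
    gamma = _median_heuristic_gamma(X)
    classes = F.classes()
    cidx = {c: i for i, c in enumerate(classes)}
    accuracies = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        correct = 0
        for train, test in skf.split(X, y):
            clf = SVC(C=cost, kernel="rbf", gamma=gamma, decision_function_shape="ovo")
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            correct += int(np.sum(pred == y[test]))
            if rep == 0:
                for yt, yp in zip(y[test], pred):
                    confusion[cidx[yt], cidx[yp]] += 1
        accuracies.append(correct / len(X))
    return float(np.mean(accuracies)), confusion


def svr_estimate(
    F: LabeledFeatures,
    folds: int = 10,
    cost: float = 10.0,
    repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold SVR predictions of the numeric target, averaged over repeats.

    Predictions are unconstrained in sign (a regression may extrapolate
    below the smallest target).  Returns one prediction per sample.
    """
    if F.numeric_targets is None:
        raise ValueError("numeric_targets required for regression")
    X, t = F.vectors, F.numeric_targets
    if np.allclose(t, t[0]):
        import warnings

        warnings.warn("constant targets: degenerate fit", stacklevel=2)
    gamma = _median_heuristic_gamma(X)
    preds = np.zeros((repeats, len(X)))
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train, test in kf.split(X):
            reg = SVR(C=cost, kernel="rbf", gamma=gamma)
            reg.fit(X[train], t[train])
            preds[rep, test] = reg.predict(X[test])
    return preds.mean(axis=0)


def speed_baseline(series: TimeSeries) -> float:
    """Mean 2-norm of consecutive-frame differences (a crude speed proxy)."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return float(np.mean(np.linalg.norm(np.diff(series.frames, axis=0), axis=1)))


def posture_std_baseline(series: TimeSeries) -> np.ndarray:
    """Per-coordinate standard deviation over frames (posture-variety proxy)."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return series.frames.std(axis=0, ddof=1)
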