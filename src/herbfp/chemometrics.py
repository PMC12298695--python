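"""Discriminant modeling core: duplex splitting, PLS, PLS-DA, CV, VIP.

The classification chain is the classical chemometric one for two-class
fingerprint screening:

* the dataset is split once by the deterministic **duplex** procedure so that
  calibration and validation sets both span the data space;
* the unfolded feature block (tens of thousands of columns) is **compressed**
  by PLS fitted on training rows, and the resulting score matrix is modeled
  again with **PLS-DA** — regression of the class codes (1 = target present,
  2 = absent) on PLS factors, thresholded at the midpoint 1.5;
* model complexity (number of PLS factors, up to 30) is chosen by stratified
  10-fold cross-validation as the smallest factor count reaching the maximum
  correct classification rate (ccr%);
* per-feature influence is summarized by VIP scores, whose squared values
  average to 1 by construction.

PLS is the univariate-response NIPALS variant: per factor the weight vector
is proportional to X'y on the deflated data, scores are orthogonal, and
predictions are accumulated factor by factor, which also yields the whole
ccr%-versus-complexity curve from a single fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DimensionError, ParameterError, StratificationError, TrainingError
from .preprocess import ColumnScaler, PreprocessSpec

POSITIVE, NEGATIVE = 1, 2
DECISION_THRESHOLD = 1.5  # midpoint of the class codes; ties go negative


# ---------------------------------------------------------------------------
# Duplex splitting


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float


def _max_distance_pair(D: np.ndarray, pool: list[int]) -> tuple[int, int]:
    sub = D[np.ix_(pool, pool)]
    np.fill_diagonal(sub, -1.0)
    best = np.argwhere(sub == sub.max())
    i, j = min((min(a, b), max(a, b)) for a, b in best)  # lexicographic tie-break
    return pool[i], pool[j]


def _farthest_from(D: np.ndarray, members: list[int], pool: list[int]) -> int:
    # maximize the minimum distance to the partition's current members
    d = D[np.ix_(pool, members)].min(axis=1)
    return pool[int(np.argmax(d))]  # argmax takes the first (lowest index) on ties


def duplex_split(X: np.ndarray, fraction: float = 0.25, ids=None) -> SplitResult:
    """Deterministic duplex split of the rows of ``X``.

    The mutually most distant pair seeds the training set, the most distant
    remaining pair seeds the test set, and the two sets then alternately claim
    the remaining point farthest (max-min Euclidean distance) from their
    current members. The surplus is directed so the test set ends with
    ``round(fraction * n)`` points.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ParameterError(f"duplex needs at least 4 samples, got {n}")
    if not 0 < fraction <= 0.5:
        raise ParameterError(f"test fraction must lie in (0, 0.5], got {fraction}")
    n_test = int(round(fraction * n))
    if n_test < 2:
        raise ParameterError(f"test quota {n_test} below the duplex seed pair size")
    D = squareform(pdist(X))
    pool = list(range(n))
    a, b = _max_distance_pair(D, pool)
    train = [a, b]
    for k in (a, b):
        pool.remove(k)
    c, d = _max_distance_pair(D, pool)
    test = [c, d]
    for k in (c, d):
        pool.remove(k)
    turn = 0  # 0 -> train, 1 -> test
    n_train = n - n_test
    while pool:
        if len(test) >= n_test:
            train.extend(pool)
            break
        if len(train) >= n_train:
            test.extend(pool)
            break
        target = train if turn == 0 else test
        nxt = _farthest_from(D, target, pool)
        target.append(nxt)
        pool.remove(nxt)
        turn = 1 - turn
    ids = list(ids) if ids is not None else list(range(n))
    train_idx = np.array(sorted(train), dtype=int)
    test_idx = np.array(sorted(test), dtype=int)
    return SplitResult(
        train_ids=[ids[i] for i in train_idx],
        test_ids=[ids[i] for i in test_idx],
        train_idx=train_idx,
        test_idx=test_idx,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# PLS (univariate response, NIPALS with deflation)


@dataclass
class PlsCore:
    """Fitted PLS decomposition: weights W, x-loadings P, y-loadings q, scores T."""

    W: np.ndarray  # (p, A)
    P: np.ndarray  # (p, A)
    q: np.ndarray  # (A,)
    T: np.ndarray  # (n, A), training scores
    x_mean: np.ndarray
    y_mean: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.q.size

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise DimensionError(
                f"data has {X.shape[1]} features, model expects {self.n_features}"
            )
        return X

    def scores(self, X: np.ndarray, A: int | None = None) -> np.ndarray:
        """Project new rows onto the first A factors (sequential deflation)."""
        A = self.n_factors if A is None else min(A, self.n_factors)
        Xc = self._check(X) - self.x_mean
        T = np.empty((Xc.shape[0], A))
        for a in range(A):
            t = Xc @ self.W[:, a]
            T[:, a] = t
            Xc = Xc - np.outer(t, self.P[:, a])
        return T

    def predict(self, X: np.ndarray, A: int | None = None) -> np.ndarray:
        """Continuous prediction using the first A factors (A=0 gives the training mean)."""
        A = self.n_factors if A is None else A
        if A == 0:
            return np.full(np.atleast_2d(X).shape[0], self.y_mean)
        return self.y_mean + self.scores(X, A) @ self.q[: min(A, self.n_factors)]

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Cumulative predictions for every complexity 1..n_factors, shape (n, A)."""
        T = self.scores(X)
        return self.y_mean + np.cumsum(T * self.q, axis=1)

    def coefficients(self, A: int | None = None) -> tuple[np.ndarray, float]:
        """Regression vector b and intercept such that yhat = X b + b0."""
        A = self.n_factors if A is None else min(A, self.n_factors)
        W, P, q = self.W[:, :A], self.P[:, :A], self.q[:A]
        b = W @ np.linalg.solve(P.T @ W, q)
        return b, float(self.y_mean - self.x_mean @ b)


def pls_fit(X: np.ndarray, y: np.ndarray, A: int) -> PlsCore:
    """Fit univariate-response PLS with up to ``A`` factors.

    A request beyond min(n - 1, p) or beyond the effective rank is truncated,
    with a note recorded in ``PlsCore.warnings``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DimensionError(f"y has {y.size} entries for {n} rows")
    if A < 0:
        raise ParameterError("number of factors must be non-negative")
    warnings: list[str] = []
    a_max = min(n - 1, p)
    if A > a_max:
        warnings.append(f"requested {A} factors, admissible maximum is {a_max}")
        A = a_max
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    x_scale = float(np.abs(Xd).max()) or 1.0
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    tol = 1e-12
    kept = 0
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= tol * x_scale * max(np.abs(yd).max(), tol):
            warnings.append(f"rank exhausted after {kept} factors")
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (tol * x_scale) ** 2:
            warnings.append(f"rank exhausted after {kept} factors")
            break
        W[:, a], T[:, a] = w, t
        P[:, a] = (Xd.T @ t) / tt
        q[a] = float(yd @ t) / tt
        Xd = Xd - np.outer(t, P[:, a])
        yd = yd - q[a] * t
        kept += 1
    return PlsCore(W=W[:, :kept], P=P[:, :kept], q=q[:kept], T=T[:, :kept],
                   x_mean=x_mean, y_mean=y_mean, warnings=warnings)


def pls_compress(X_train: np.ndarray, y_train: np.ndarray, X_other: np.ndarray | None,
                 k: int) -> tuple[np.ndarray, np.ndarray | None, PlsCore]:
    """Compress a wide block to k PLS score columns, fitted on training rows only.

    Returns training scores, the projection of the other rows onto the same
    weights, and the fitted compressor.
    """
    core = pls_fit(X_train, y_train, k)
    scores_other = core.scores(X_other) if X_other is not None else None
    return core.T.copy(), scores_other, core


def vip_scores(core: PlsCore, A: int | None = None) -> np.ndarray:
    """Variable importance in projection for the first A factors.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a the y-variance explained by factor a; mean squared VIP is 1.
    """
    A = core.n_factors if A is None else min(A, core.n_factors)
    if A < 1:
        raise ParameterError("VIP needs at least one fitted factor")
    W = core.W[:, :A]
    ssy = core.q[:A] ** 2 * np.einsum("ij,ij->j", core.T[:, :A], core.T[:, :A])
    total = ssy.sum()
    if total <= 0:
        raise ParameterError("VIP undefined: the model explains no response variance")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = core.n_features
    return np.sqrt(p * (wn**2 @ ssy) / total)


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class PlsdaModel:
    """Classifier state: optional compressor, discriminant PLS core, decision rule."""

    core: PlsCore
    n_factors: int
    compressor: PlsCore | None = None
    threshold: float = DECISION_THRESHOLD
    preprocess: PreprocessSpec | None = None
    scaler: ColumnScaler | None = None
    n_time: int | None = None

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.preprocess is not None:
            X = self.preprocess.apply_rowwise(X, self.n_time)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if self.compressor is not None:
            X = self.compressor.scores(X)
        return X

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.core.predict(self._features(X), self.n_factors)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return codes_from_values(self.decision_values(X), self.threshold)


def codes_from_values(yhat: np.ndarray, threshold: float = DECISION_THRESHOLD) -> np.ndarray:
    """Threshold continuous predictions: below the midpoint is the positive class 1,
    at or above it the negative class 2 (ties resolve to 'absent')."""
    return np.where(np.asarray(yhat) < threshold, POSITIVE, NEGATIVE)


def plsda_fit(X_train: np.ndarray, y_train: np.ndarray, A: int, k_compress: int | None = None,
              preprocess: PreprocessSpec | None = None, n_time: int | None = None) -> PlsdaModel:
    """Fit the (optionally compressed) PLS-DA classifier on training rows only."""
    y_train = np.asarray(y_train, dtype=float)
    if np.unique(y_train).size < 2:
        raise TrainingError("training data holds a single class")
    Xf = np.asarray(X_train, dtype=float)
    scaler = None
    if preprocess is not None:
        Xf = preprocess.apply_rowwise(Xf, n_time)
        scaler = preprocess.fit_scaler(Xf)
        if scaler is not None:
            Xf = scaler.transform(Xf)
    compressor = None
    if k_compress is not None:
        _, _, compressor = pls_compress(Xf, y_train, None, k_compress)
        Xf = compressor.T
    core = pls_fit(Xf, y_train, A)
    return PlsdaModel(core=core, n_factors=core.n_factors, compressor=compressor,
                      preprocess=preprocess, scaler=scaler, n_time=n_time)


def plsda_predict(model: PlsdaModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CvResult:
    ccr_curve: np.ndarray  # percent, index a-1 -> a factors
    chosen_a: int
    predictions: np.ndarray  # (n, max_A) class codes from held-out folds
    fold_of: np.ndarray
    seed: int

    @property
    def best_ccr(self) -> float:
        return float(self.ccr_curve[self.chosen_a - 1])


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Balanced stratified fold assignment.

    Each class's members are shuffled and dealt one at a time to the currently
    smallest fold, so fold sizes never differ by more than one even when a
    class is rarer than the fold count. Raises if any fold's TRAINING side
    would lose a class entirely.
    """
    y = np.asarray(y)
    n = y.size
    if folds < 2 or folds > n:
        raise ParameterError(f"fold count {folds} invalid for {n} samples")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    sizes = np.zeros(folds, dtype=int)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        for m in members:
            f = int(np.lexsort((np.arange(folds), sizes))[0])
            fold_of[m] = f
            sizes[f] += 1
    for f in range(folds):
        train_classes = np.unique(y[fold_of != f])
        if train_classes.size < np.unique(y).size:
            raise StratificationError(f"fold {f}: training part lost a class")
    return fold_of


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_A: int = 30,
    folds: int = 10,
    spec: PreprocessSpec | None = None,
    k_compress: int | None = None,
    seed: int = 0,
    n_time: int | None = None,
) -> CvResult:
    """Stratified k-fold CV of the compressed PLS-DA chain over 1..max_A factors.

    Within each fold, column statistics, the compressor and the discriminant
    PLS are all re-fit on the fold's training rows only. The stateless
    row-wise pretreatment steps are applied up front (they use no cross-sample
    statistics, so this cannot leak). Returns the pooled ccr% curve and the
    smallest factor count attaining its maximum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_A < 1:
        raise ParameterError("max_A must be at least 1")
    Xr = spec.apply_rowwise(X, n_time) if spec is not None else X
    fold_of = stratified_folds(y, folds, seed)
    n = y.size
    preds = np.empty((n, max_A), dtype=int)
    for f in range(folds):
        va = fold_of == f
        tr = ~va
        if not va.any():
            continue
        Xtr, Xva = Xr[tr], Xr[va]
        scaler = spec.fit_scaler(Xtr) if spec is not None else None
        if scaler is not None:
            Xtr, Xva = scaler.transform(Xtr), scaler.transform(Xva)
        if k_compress is not None:
            Xtr, Xva, _ = pls_compress(Xtr, y[tr], Xva, k_compress)
        core = pls_fit(Xtr, y[tr], min(max_A, int(tr.sum()) - 1, Xtr.shape[1]))
        path = core.predict_path(Xva)  # (n_va, A_fit)
        if path.shape[1] == 0:
            path = np.full((int(va.sum()), 1), core.y_mean)
        if path.shape[1] < max_A:  # complexity capped by fold rank: extend flat
            path = np.hstack([path, np.repeat(path[:, -1:], max_A - path.shape[1], axis=1)])
        preds[va] = codes_from_values(path)
    ccr_curve = 100.0 * (preds == y[:, None]).mean(axis=0)
    chosen = int(np.argmax(ccr_curve)) + 1  # argmax returns the first = smallest A
    return CvResult(ccr_curve=ccr_curve, chosen_a=chosen, predictions=preds,
                    fold_of=fold_of, seed=seed)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class StageReport:
    """Confusion counts and ccr% for one validation stage."""

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    misclassified: list
    ccr: float  # raw percent
    ccr_pct: int  # rounded to integer percent for reporting

    @classmethod
    def from_predictions(cls, y_true, y_pred, ids=None) -> "StageReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.size == 0:
            raise ParameterError("cannot evaluate an empty partition")
        ids = list(ids) if ids is not None else list(range(y_true.size))
        tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
        fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
        tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
        fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
        ccr = 100.0 * (tp + tn) / y_true.size
        wrong = [ids[i] for i in np.flatnonzero(y_true != y_pred)]
        return cls(n=y_true.size, tp=tp, fp=fp, tn=tn, fn=fn, misclassified=wrong,
                   ccr=ccr, ccr_pct=int(round(ccr)))

    @classmethod
    def from_confusion(cls, tp: int, fp: int, tn: int, fn: int) -> "StageReport":
        n = tp + fp + tn + fn
        if n == 0:
            raise ParameterError("empty confusion matrix")
        ccr = 100.0 * (tp + tn) / n
        return cls(n=n, tp=tp, fp=fp, tn=tn, fn=fn, misclassified=[],
                   ccr=ccr, ccr_pct=int(round(ccr)))


@dataclass
class EvaluationReport:
    """ccr% for calibration / cross-validation / external test, Tables-style."""

    calibration: StageReport | None = None
    cv: StageReport | None = None
    test: StageReport | None = None
    chosen_factors: int | None = None
    preprocessing_label: str = ""
    cv_curve: np.ndarray | None = None
    split_signature: tuple = ()

    def row(self) -> dict:
        blank = ""
        return {
            "preprocessing": self.preprocessing_label or blank,
            "pls_factors": self.chosen_factors if self.chosen_factors is not None else blank,
            "ccr_cv": self.cv.ccr_pct if self.cv else blank,
            "ccr_calibration": self.calibration.ccr_pct if self.calibration else blank,
            "ccr_test": self.test.ccr_pct if self.test else blank,
        }


def evaluate(model: PlsdaModel, X_test: np.ndarray, y_test: np.ndarray, ids=None) -> StageReport:
    """External-test evaluation of a fitted classifier."""
    return StageReport.from_predictions(y_test, model.predict(X_test), ids)
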