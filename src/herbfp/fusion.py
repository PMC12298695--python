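"""Mid- and high-level fusion of two detector blocks over the same samples.

Two instruments (e.g. a diode-array detector and a mass spectrometer) measure
the same sample set with very different feature dimensions. Fusion gives the
blocks equal weight in one matrix before discriminant modeling:

* **mid-level** — unsupervised per-block feature extraction: PCA fitted on the
  training rows of each block, the leading scores kept, scaled, concatenated;
* **high-level** — supervised per-block compression: PLS scores per block
  (fitted on training rows and labels), scaled, concatenated;
* **low-level** — plain concatenation of the raw blocks, kept only as a
  baseline so comparison tables are complete.

After scaling, each block's score columns contribute equal total variance
(1 per block, split evenly over the block's columns) regardless of how many
components each block kept. Block compressors are always fitted on training
rows only, including inside cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chemometrics import CvResult, EvaluationReport, codes_from_values, pls_fit, stratified_folds
from .errors import ComparabilityError, GridError, ParameterError


@dataclass
class FusionConfig:
    """level: 'mid' (PCA per block), 'high' (PLS per block) or 'low' (concatenate).

    ``per_block_components`` fixes the per-block score count; when None the
    mid-level path keeps the components explaining ``variance_explained`` of
    the training variance, and the high-level path keeps ``k_high`` factors.
    """

    level: str = "high"
    per_block_components: int | None = None
    variance_explained: float = 0.95
    k_high: int = 10

    def __post_init__(self) -> None:
        if self.level not in {"mid", "high", "low"}:
            raise ParameterError(f"unknown fusion level {self.level!r}")
        if self.per_block_components is not None and self.per_block_components < 1:
            raise ParameterError("per_block_components must be >= 1")


@dataclass
class _BlockState:
    kind: str  # "pca" | "pls" | "raw"
    mean: np.ndarray | None = None
    basis: np.ndarray | None = None  # (p, k) projection for PCA
    pls_core: object | None = None
    score_mean: np.ndarray | None = None
    score_scale: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "raw":
            S = np.asarray(X, dtype=float)
        elif self.kind == "pca":
            S = (np.asarray(X, dtype=float) - self.mean) @ self.basis
        else:
            S = self.pls_core.scores(X)
        return (S - self.score_mean) / self.score_scale


@dataclass
class FusionState:
    config: FusionConfig
    blocks: list[_BlockState]

    def transform(self, blocks_new: list[np.ndarray]) -> np.ndarray:
        if len(blocks_new) != len(self.blocks):
            raise GridError("number of blocks differs from the fitted fusion state")
        return np.hstack([b.transform(X) for b, X in zip(self.blocks, blocks_new)])


def _check_blocks(blocks: list[np.ndarray]) -> list[np.ndarray]:
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    if len(blocks) != 2:
        raise ParameterError(f"fusion expects exactly two blocks, got {len(blocks)}")
    if blocks[0].shape[0] != blocks[1].shape[0]:
        raise GridError(
            f"blocks disagree on the sample set: {blocks[0].shape[0]} vs {blocks[1].shape[0]} rows"
        )
    return blocks


def _scale_scores(S: np.ndarray, k_block: int) -> tuple[np.ndarray, np.ndarray]:
    """Train-set scaling giving each block total variance 1 across its columns."""
    mean = S.mean(axis=0)
    sd = S.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    return mean, sd * np.sqrt(k_block)


def _fit_pca_block(X: np.ndarray, config: FusionConfig) -> _BlockState:
    n, p = X.shape
    cap = min(n - 1, p)
    pca = PCA(n_components=cap, svd_solver="full").fit(X)
    ev = pca.explained_variance_
    rank = int(np.sum(ev > ev[0] * 1e-12)) if ev.size else 0
    warnings = []
    if config.per_block_components is not None:
        k = config.per_block_components
        if k > rank:
            warnings.append(f"requested {k} components, block rank is {rank}; truncated")
            k = rank
    else:
        cum = np.cumsum(ev[:rank]) / ev[:rank].sum()
        k = int(np.searchsorted(cum, config.variance_explained) + 1)
    basis = pca.components_[:k].T.copy()  # (p, k)
    # reproducible sign: largest-magnitude loading of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(basis[:, j])))
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
    state = _BlockState(kind="pca", mean=pca.mean_, basis=basis, warnings=warnings)
    S = (X - pca.mean_) @ basis
    state.score_mean, state.score_scale = _scale_scores(S, k)
    return state


def _fit_pls_block(X: np.ndarray, y: np.ndarray, config: FusionConfig) -> _BlockState:
    k = config.per_block_components or config.k_high
    core = pls_fit(X, y, k)
    state = _BlockState(kind="pls", pls_core=core, warnings=list(core.warnings))
    state.score_mean, state.score_scale = _scale_scores(core.T, core.n_factors)
    return state


def _fit_raw_block(X: np.ndarray) -> _BlockState:
    state = _BlockState(kind="raw")
    state.score_mean, state.score_scale = _scale_scores(X, X.shape[1])
    return state


def fuse_mid(blocks_train: list[np.ndarray], config: FusionConfig | None = None,
             blocks_other: list[np.ndarray] | None = None
             ) -> tuple[np.ndarray, np.ndarray | None, FusionState]:
    """Mid-level fusion: per-block PCA scores (train-fitted), scaled, concatenated."""
    config = config or FusionConfig(level="mid")
    if config.level != "mid":
        raise ParameterError(f"fuse_mid called with level {config.level!r}")
    blocks_train = _check_blocks(blocks_train)
    state = FusionState(config=config, blocks=[_fit_pca_block(b, config) for b in blocks_train])
    fused_train = state.transform(blocks_train)
    fused_other = state.transform(_check_blocks(blocks_other)) if blocks_other is not None else None
    return fused_train, fused_other, state


def fuse_high(blocks_train: list[np.ndarray], y_train: np.ndarray,
              config: FusionConfig | None = None,
              blocks_other: list[np.ndarray] | None = None
              ) -> tuple[np.ndarray, np.ndarray | None, FusionState]:
    """High-level fusion: per-block supervised PLS compression, scaled, concatenated."""
    config = config or FusionConfig(level="high")
    if config.level != "high":
        raise ParameterError(f"fuse_high called with level {config.level!r}")
    blocks_train = _check_blocks(blocks_train)
    y_train = np.asarray(y_train, dtype=float)
    state = FusionState(config=config,
                        blocks=[_fit_pls_block(b, y_train, config) for b in blocks_train])
    fused_train = state.transform(blocks_train)
    fused_other = state.transform(_check_blocks(blocks_other)) if blocks_other is not None else None
    return fused_train, fused_other, state


def fuse_low(blocks_train: list[np.ndarray], blocks_other: list[np.ndarray] | None = None
             ) -> tuple[np.ndarray, np.ndarray | None, FusionState]:
    """Low-level baseline: block-scaled raw concatenation (no compression)."""
    blocks_train = _check_blocks(blocks_train)
    state = FusionState(config=FusionConfig(level="low"),
                        blocks=[_fit_raw_block(b) for b in blocks_train])
    fused_train = state.transform(blocks_train)
    fused_other = state.transform(_check_blocks(blocks_other)) if blocks_other is not None else None
    return fused_train, fused_other, state


def fused_cross_validate(blocks: list[np.ndarray], y: np.ndarray,
                         config: FusionConfig | None = None, max_A: int = 30,
                         folds: int = 10, seed: int = 0) -> CvResult:
    """CV of the fused PLS-DA chain with the block compressors re-fit per fold."""
    blocks = _check_blocks(blocks)
    y = np.asarray(y, dtype=float).ravel()
    config = config or FusionConfig()
    fold_of = stratified_folds(y, folds, seed)
    n = y.size
    preds = np.empty((n, max_A), dtype=int)
    for f in range(folds):
        va = fold_of == f
        tr = ~va
        btr = [b[tr] for b in blocks]
        bva = [b[va] for b in blocks]
        if config.level == "mid":
            Xtr, Xva, _ = fuse_mid(btr, config, bva)
        elif config.level == "high":
            Xtr, Xva, _ = fuse_high(btr, y[tr], config, bva)
        else:
            Xtr, Xva, _ = fuse_low(btr, bva)
        core = pls_fit(Xtr, y[tr], min(max_A, int(tr.sum()) - 1, Xtr.shape[1]))
        path = core.predict_path(Xva)
        if path.shape[1] == 0:
            path = np.full((int(va.sum()), 1), core.y_mean)
        if path.shape[1] < max_A:
            path = np.hstack([path, np.repeat(path[:, -1:], max_A - path.shape[1], axis=1)])
        preds[va] = codes_from_values(path)
    ccr_curve = 100.0 * (preds == y[:, None]).mean(axis=0)
    chosen = int(np.argmax(ccr_curve)) + 1
    return CvResult(ccr_curve=ccr_curve, chosen_a=chosen, predictions=preds,
                    fold_of=fold_of, seed=seed)


def compare_models(reports: list[EvaluationReport], labels: list[str]) -> pd.DataFrame:
    """Side-by-side grid of model statistics (preprocessing, factors, ccr% per stage).

    Reports carrying a split signature must agree on it — models evaluated on
    different splits are not comparable.
    """
    if len(reports) != len(labels):
        raise ParameterError("one label per report, please")
    signatures = {r.split_signature for r in reports if r.split_signature}
    if len(signatures) > 1:
        raise ComparabilityError("reports were built on different train/test splits")
    rows = []
    for label, rep in zip(labels, reports):
        row = {"model": label}
        row.update(rep.row())
        rows.append(row)
    return pd.DataFrame(rows, columns=["model", "preprocessing", "pls_factors",
                                       "ccr_cv", "ccr_calibration", "ccr_test"])
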