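"""End-to-end training, screening of unknowns, and model persistence.

The training chain reproduces the screening workflow for one target plant:

    fingerprint region selection -> common-grid cube -> COW alignment to the
    reference chromatogram -> unfolding -> row-wise pretreatment -> duplex
    75/25 split -> column scaling + PLS compression (train rows only) ->
    10-fold CV over 1..30 factors -> final PLS-DA fit -> external test.

A trained :class:`ScreeningModel` is self-contained: it stores the time grid,
the reference trace (so unknowns can be warped the same way), the pretreatment
recipe with its fitted statistics, the compressor and the discriminant core —
prediction needs no training data. Screening unknowns against several
per-plant models yields a verdict table ("Present" / "—" per target) with
discrepancy flags against the claims on the packaging.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .alignment import (
    CowParams,
    align_channels,
    align_cube,
    cow_grid_search,
    most_representative_reference,
)
from .dataset_io import Dataset, Fingerprint, FingerprintCube, build_cube, select_region, unfold
from .errors import GridError, ParameterError, TrainingError
from .preprocess import ColumnScaler, PreprocessSpec, resolve_spec

PRESENT, ABSENT = "Present", "—"


@dataclass
class PipelineConfig:
    """Everything the training run needs, with screening-study defaults.

    ``preprocess`` may be a single recipe (registry key, dict or
    PreprocessSpec) or a list of candidates; with a list, each candidate is
    cross-validated and the one with the best CV ccr% (tie: first listed)
    wins. ``cow_segment_grid``/``cow_slack_grid`` switch alignment to a grid
    search; by default a single fixed (segment, slack) pair is used.
    """

    region: tuple[float, float] = (3.0, 10.0)
    align: bool = True
    cow_segment: int = 50
    cow_slack: int = 1
    cow_preshift_frac: float = 0.05  # coarse-lag bound as a fraction of the grid length
    cow_segment_grid: tuple[int, ...] | None = None
    cow_slack_grid: tuple[int, ...] | None = None
    reference_policy: str = "representative"  # warp target: "representative" | "designated"
    reference_id: str | None = None  # default: the manifest's reference sample
    preprocess: object = ("sg1-intensity", "sg1", "none")  # CV picks; ties -> first
    test_fraction: float = 0.25
    k_compress: int = 30
    max_factors: int = 30
    folds: int = 10
    cv_seed: int = 0
    target: str = "target"


@dataclass
class ScreeningModel:
    """Self-contained per-plant binary model (everything prediction replays)."""

    target: str
    region: tuple[float, float]
    time_grid: np.ndarray
    reference_signal: np.ndarray | None
    cow_params: CowParams | None
    preprocess: PreprocessSpec
    scaler: ColumnScaler | None
    compressor: chem.PlsCore | None
    core: chem.PlsCore
    n_factors: int
    preshift_max: int = 0
    threshold: float = chem.DECISION_THRESHOLD
    cv_seed: int = 0
    manifest_sha256: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def n_time(self) -> int:
        return self.time_grid.size


def _manifest_hash(manifest: pd.DataFrame) -> str:
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()


def prepare_matrix(dataset: Dataset, config: PipelineConfig):
    """Region-select, assemble, align and unfold a labeled dataset.

    Returns (unfolded matrix, class vector, reference id, cow params used).
    """
    fps = [select_region(fp, *config.region) for fp in dataset.fingerprints]
    ref_id = config.reference_id
    if ref_id is None:
        refs = dataset.manifest.loc[dataset.manifest["role"] == "reference", "sample_id"]
        ref_id = str(refs.iloc[0]) if len(refs) else fps[0].sample_id
    cube = build_cube(fps, reference_id=ref_id)
    params = None
    preshift_max = int(round(config.cow_preshift_frac * cube.n_timepoints))
    if config.align:
        # the warp target: the chromatogram every run is warped onto. The
        # "representative" policy (most correlated to all others) gives blanks
        # and triturations alike shared structure to lock onto; "designated"
        # warps onto the reference-plant run itself.
        if config.reference_policy == "representative":
            warp_ref = most_representative_reference(cube)
        else:
            warp_ref = ref_id
        if config.cow_segment_grid and config.cow_slack_grid:
            ref_trace = cube.intensity(warp_ref)
            params, _ = cow_grid_search(cube.values[:, 0, :].T, ref_trace,
                                        config.cow_segment_grid, config.cow_slack_grid)
            params = replace(params, reference_id=warp_ref)
        else:
            params = CowParams(config.cow_segment, config.cow_slack, reference_id=warp_ref)
        cube = align_cube(cube, params, preshift_max=preshift_max)
    return unfold(cube), dataset.classes(), ref_id, params, preshift_max


def train_model(dataset: Dataset, config: PipelineConfig | None = None
                ) -> tuple[ScreeningModel, chem.EvaluationReport]:
    """Run the whole training chain and evaluate on the held-out duplex test set."""
    config = config or PipelineConfig()
    y_all = dataset.classes()
    if np.unique(y_all).size < 2:
        raise TrainingError("dataset holds a single class; cannot train a discriminant model")
    um, y_all, ref_id, cow_params, preshift_max = prepare_matrix(dataset, config)
    n_time = um.n_timepoints
    candidates = config.preprocess if isinstance(config.preprocess, (list, tuple)) \
        else [config.preprocess]
    specs = [resolve_spec(s) for s in candidates]

    # duplex split on the first candidate's row-wise pretreated rows: distances in
    # the modeling space, but using no statistics that would need a training set
    X_dist = specs[0].apply_rowwise(um.X, n_time)
    split = chem.duplex_split(X_dist, config.test_fraction, ids=um.sample_ids)
    Xtr_raw, Xte_raw = um.X[split.train_idx], um.X[split.test_idx]
    ytr, yte = y_all[split.train_idx], y_all[split.test_idx]

    folds = min(config.folds, len(split.train_ids))
    best: tuple[chem.CvResult, PreprocessSpec] | None = None
    for spec in specs:
        cv = chem.cross_validate(Xtr_raw, ytr, max_A=config.max_factors, folds=folds,
                                 spec=spec, k_compress=config.k_compress,
                                 seed=config.cv_seed, n_time=n_time)
        if best is None or cv.best_ccr > best[0].best_ccr + 1e-12:
            best = (cv, spec)
    cv, spec = best

    model_cls = chem.plsda_fit(Xtr_raw, ytr, A=cv.chosen_a, k_compress=config.k_compress,
                               preprocess=spec, n_time=n_time)
    report = chem.EvaluationReport(
        calibration=chem.StageReport.from_predictions(
            ytr, model_cls.predict(Xtr_raw), split.train_ids),
        cv=chem.StageReport.from_predictions(
            ytr, cv.predictions[:, cv.chosen_a - 1], split.train_ids),
        test=chem.StageReport.from_predictions(yte, model_cls.predict(Xte_raw), split.test_ids),
        chosen_factors=cv.chosen_a,
        preprocessing_label=spec.label,
        cv_curve=cv.ccr_curve,
        split_signature=tuple(split.test_ids),
    )
    ref_trace = None
    if cow_params is not None:
        ref_idx = um.sample_ids.index(cow_params.reference_id)
        ref_trace = um.X[ref_idx, :n_time].copy()
    model = ScreeningModel(
        target=config.target,
        region=tuple(config.region),
        time_grid=um.time_grid.copy(),
        reference_signal=ref_trace,
        cow_params=cow_params,
        preprocess=spec,
        scaler=model_cls.scaler,
        compressor=model_cls.compressor,
        core=model_cls.core,
        n_factors=model_cls.n_factors,
        preshift_max=preshift_max if cow_params is not None else 0,
        cv_seed=config.cv_seed,
        manifest_sha256=_manifest_hash(dataset.manifest),
        warnings=list(model_cls.core.warnings),
    )
    return model, report


# ---------------------------------------------------------------------------
# Prediction / screening


def _fingerprint_row(model: ScreeningModel, fp: Fingerprint) -> np.ndarray:
    """Replay the stored pipeline on one unknown: region, grid, warp, unfold row."""
    sel = select_region(fp, *model.region)
    lo, hi = model.time_grid[0], model.time_grid[-1]
    if sel.times[0] > lo + 1e-9 or sel.times[-1] < hi - 1e-9:
        raise GridError(
            f"{fp.sample_id}: fingerprint span {sel.span} does not cover the "
            f"model grid [{lo}, {hi}]"
        )
    intensity = np.interp(model.time_grid, sel.times, sel.intensities)
    mass = np.interp(model.time_grid, sel.times, sel.masses)
    if model.cow_params is not None and model.reference_signal is not None:
        intensity, mass, _, _ = align_channels(intensity, mass, model.reference_signal,
                                               model.cow_params, model.preshift_max)
    return np.concatenate([intensity, mass])


def decision_values(model: ScreeningModel, fps: list[Fingerprint]) -> np.ndarray:
    X = np.vstack([_fingerprint_row(model, fp) for fp in fps])
    X = model.preprocess.apply_rowwise(X, model.n_time)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    if model.compressor is not None:
        X = model.compressor.scores(X)
    return model.core.predict(X, model.n_factors)


def predict_fingerprints(model: ScreeningModel, fps: list[Fingerprint]) -> np.ndarray:
    """Class codes (1 present / 2 absent) for a list of unknowns."""
    return chem.codes_from_values(decision_values(model, fps), model.threshold)


def screen_unknowns(models: dict[str, ScreeningModel], fps: list[Fingerprint],
                    claims: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Screen unknowns against several per-plant models.

    Returns one row per sample with a Present/— call per model, the claimed
    plants, and discrepancy flags (``claimed-but-absent:X``,
    ``present-but-unclaimed:X``).
    """
    claims = claims or {}
    calls = {name: predict_fingerprints(m, fps) for name, m in models.items()}
    rows = []
    for i, fp in enumerate(fps):
        claimed = set(claims.get(fp.sample_id, set()))
        row = {"sample_id": fp.sample_id, "claimed": ";".join(sorted(claimed))}
        flags = []
        for name in models:
            present = calls[name][i] == chem.POSITIVE
            row[name] = PRESENT if present else ABSENT
            if name in claimed and not present:
                flags.append(f"claimed-but-absent:{name}")
            if present and claimed and name not in claimed:
                flags.append(f"present-but-unclaimed:{name}")
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence (single .npz archive; metadata as an embedded JSON string)


def _core_arrays(prefix: str, core: chem.PlsCore | None) -> dict:
    if core is None:
        return {}
    return {
        f"{prefix}_W": core.W, f"{prefix}_P": core.P, f"{prefix}_q": core.q,
        f"{prefix}_T": core.T, f"{prefix}_xmean": core.x_mean,
        f"{prefix}_ymean": np.array([core.y_mean]),
    }


def _core_from(prefix: str, data) -> chem.PlsCore | None:
    if f"{prefix}_W" not in data:
        return None
    return chem.PlsCore(
        W=data[f"{prefix}_W"], P=data[f"{prefix}_P"], q=data[f"{prefix}_q"],
        T=data[f"{prefix}_T"], x_mean=data[f"{prefix}_xmean"],
        y_mean=float(data[f"{prefix}_ymean"][0]),
    )


def save_model(model: ScreeningModel, path) -> None:
    meta = {
        "target": model.target,
        "region": list(model.region),
        "cow": None if model.cow_params is None else
            {"segment_length": model.cow_params.segment_length,
             "slack": model.cow_params.slack,
             "reference_id": model.cow_params.reference_id},
        "preprocess": model.preprocess.to_dict(),
        "n_factors": model.n_factors,
        "preshift_max": model.preshift_max,
        "threshold": model.threshold,
        "cv_seed": model.cv_seed,
        "manifest_sha256": model.manifest_sha256,
        "warnings": model.warnings,
        "has_scaler": model.scaler is not None,
    }
    arrays = {"time_grid": model.time_grid, "meta": np.array(json.dumps(meta))}
    if model.reference_signal is not None:
        arrays["reference_signal"] = model.reference_signal
    if model.scaler is not None:
        arrays["scaler_mean"] = model.scaler.mean
        arrays["scaler_scale"] = model.scaler.scale
    arrays.update(_core_arrays("compressor", model.compressor))
    arrays.update(_core_arrays("core", model.core))
    np.savez_compressed(path, **arrays)


def load_model(path) -> ScreeningModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cow = meta["cow"]
        core = _core_from("core", data)
        if core is None:
            raise ParameterError(f"{path}: not a herbfp model file")
        return ScreeningModel(
            target=meta["target"],
            region=tuple(meta["region"]),
            time_grid=data["time_grid"],
            reference_signal=data["reference_signal"] if "reference_signal" in data else None,
            cow_params=None if cow is None else CowParams(**cow),
            preprocess=PreprocessSpec.from_dict(meta["preprocess"]),
            scaler=ColumnScaler(mean=data["scaler_mean"], scale=data["scaler_scale"])
            if meta["has_scaler"] else None,
            compressor=_core_from("compressor", data),
            core=core,
            n_factors=int(meta["n_factors"]),
            preshift_max=int(meta.get("preshift_max", 0)),
            threshold=float(meta["threshold"]),
            cv_seed=int(meta["cv_seed"]),
            manifest_sha256=meta["manifest_sha256"],
            warnings=list(meta["warnings"]),
        )
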