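"""Fingerprint containers, CSV I/O, cube assembly and unfolding.

A *fingerprint* is one sample's chromatographic run exported as three parallel
vectors: retention time (minutes), base-peak m/z per time point, and summed
intensity. Fingerprints are assembled onto a shared time grid into a 3-D
*cube* (timepoints x 2 channels x samples) and unfolded into the flat
samples x (2 x timepoints) matrix that the classifiers consume: all intensity
features first (time-ordered), then all mass features.

The mass channel is treated as a plain numeric channel throughout — including
linear interpolation onto the shared grid — even though base-peak m/z is
categorical per scan. This mirrors how the cube keeps mass as an ordinary
data column; the classifier sees mass flips between components as sharp
numeric steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GridError, RegionError

FINGERPRINT_COLUMNS = ("time_min", "mz_basepeak", "intensity")
MANIFEST_COLUMNS = ("sample_id", "role", "matrix_id", "ratio", "class")
CHANNELS = ("intensity", "mass")


@dataclass
class Fingerprint:
    """One sample's (time, base-peak m/z, intensity) series plus identity metadata.

    Invariants enforced at construction: equal vector lengths, strictly
    increasing times, finite non-negative intensities.
    """

    sample_id: str
    times: np.ndarray
    intensities: np.ndarray
    masses: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.times.size
        if self.intensities.size != n or self.masses.size != n:
            raise FormatError(
                f"{self.sample_id}: times/intensities/masses lengths differ "
                f"({n}/{self.intensities.size}/{self.masses.size})"
            )
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            bad = int(np.argmin(np.diff(self.times) > 0))
            raise FormatError(f"{self.sample_id}: times not strictly increasing at row {bad + 1}")
        if not np.all(np.isfinite(self.intensities)):
            bad = int(np.argmin(np.isfinite(self.intensities)))
            raise FormatError(f"{self.sample_id}: non-finite intensity at row {bad}")
        if np.any(self.intensities < 0):
            bad = int(np.argmax(self.intensities < 0))
            raise FormatError(f"{self.sample_id}: negative intensity at row {bad}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class FingerprintCube:
    """Aligned 3-D block: timepoints x 2 channels (intensity, mass) x samples."""

    time_grid: np.ndarray
    sample_ids: list[str]
    values: np.ndarray  # (timepoints, 2, n_samples)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        t, c, s = self.values.shape
        if t != self.time_grid.size:
            raise GridError(f"cube values have {t} timepoints but grid has {self.time_grid.size}")
        if c != 2:
            raise GridError(f"cube must have exactly 2 channels, got {c}")
        if s != len(self.sample_ids):
            raise GridError(f"cube has {s} sample slices for {len(self.sample_ids)} ids")
        if s < 2:
            raise GridError("a cube needs at least 2 samples")

    @property
    def n_timepoints(self) -> int:
        return self.time_grid.size

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in cube") from None

    def intensity(self, sample_id: str) -> np.ndarray:
        return self.values[:, 0, self.sample_index(sample_id)]


@dataclass
class UnfoldedMatrix:
    """Sample x feature matrix: columns are (intensity, t0..tN) then (mass, t0..tN)."""

    X: np.ndarray  # (n_samples, 2 * timepoints)
    sample_ids: list[str]
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.X.shape[0] != len(self.sample_ids):
            raise GridError("row count does not match sample ids")
        if self.X.shape[1] != 2 * self.time_grid.size:
            raise GridError(
                f"unfolded matrix has {self.X.shape[1]} columns, expected "
                f"2 x {self.time_grid.size}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.time_grid.size

    def feature_labels(self) -> list[tuple[str, int]]:
        t = self.time_grid.size
        return [("intensity", i) for i in range(t)] + [("mass", i) for i in range(t)]


@dataclass
class Dataset:
    """Fingerprints plus their manifest (sample_id, role, matrix_id, ratio, class)."""

    fingerprints: list[Fingerprint]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [fp.sample_id for fp in self.fingerprints]
        if list(self.manifest["sample_id"]) != ids:
            raise FormatError("manifest order does not match fingerprint order")

    def __len__(self) -> int:
        return len(self.fingerprints)

    def classes(self) -> np.ndarray:
        return self.manifest["class"].to_numpy(dtype=int)

    def by_id(self, sample_id: str) -> Fingerprint:
        for fp in self.fingerprints:
            if fp.sample_id == sample_id:
                return fp
        raise KeyError(f"sample {sample_id!r} not in dataset")


# ---------------------------------------------------------------------------
# CSV I/O


def read_fingerprint_csv(path, sample_id: str | None = None, metadata: dict | None = None) -> Fingerprint:
    """Read one per-sample CSV (header ``time_min,mz_basepeak,intensity``).

    Rows are sorted by time; exact duplicate time stamps are rejected with the
    offending row named. Non-numeric cells raise :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FINGERPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    for col in FINGERPRINT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise FormatError(f"{path.name}: non-numeric value in column {col!r} at data row {row}")
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise FormatError(f"{path.name}: empty cell in column {col!r} at data row {row}")
        df[col] = coerced
    order = np.argsort(df["time_min"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    dup = np.flatnonzero(np.diff(df["time_min"].to_numpy()) == 0)
    if dup.size:
        raise FormatError(f"{path.name}: duplicated time stamp at data row {int(dup[0]) + 1}")
    return Fingerprint(
        sample_id=sample_id or path.stem,
        times=df["time_min"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        masses=df["mz_basepeak"].to_numpy(),
        metadata=dict(metadata or {}),
    )


def write_fingerprint_csv(fp: Fingerprint, path) -> None:
    df = pd.DataFrame(
        {"time_min": fp.times, "mz_basepeak": fp.masses, "intensity": fp.intensities}
    )
    # %.17g guarantees binary round-trip for float64
    df.to_csv(path, index=False, float_format="%.17g")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    df["class"] = df["class"].astype(int)
    return df


def write_dataset(dataset: Dataset, directory) -> None:
    """Write a dataset directory: ``manifest.csv`` plus one CSV per sample."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.manifest.to_csv(directory / "manifest.csv", index=False)
    for fp in dataset.fingerprints:
        write_fingerprint_csv(fp, directory / f"{fp.sample_id}.csv")


def read_dataset(directory) -> Dataset:
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    fps = []
    for row in manifest.to_dict("records"):
        meta = {
            "role": row["role"],
            "matrix_id": row["matrix_id"],
            "ratio": row["ratio"],
            "class": int(row["class"]),
        }
        fps.append(
            read_fingerprint_csv(directory / f"{row['sample_id']}.csv", row["sample_id"], meta)
        )
    return Dataset(fingerprints=fps, manifest=manifest)


# ---------------------------------------------------------------------------
# Region selection, cube assembly, unfolding


def select_region(fp: Fingerprint, start: float, end: float) -> Fingerprint:
    """Keep the closed time interval [start, end]; everything else is dropped."""
    if start >= end:
        raise RegionError(f"region start {start} must be below end {end}")
    mask = (fp.times >= start) & (fp.times <= end)
    if not mask.any():
        raise RegionError(
            f"{fp.sample_id}: region [{start}, {end}] selects no points from span {fp.span}"
        )
    return Fingerprint(
        sample_id=fp.sample_id,
        times=fp.times[mask],
        intensities=fp.intensities[mask],
        masses=fp.masses[mask],
        metadata=dict(fp.metadata),
    )


def build_cube(
    fps: list[Fingerprint],
    reference_id: str | None = None,
    grid: np.ndarray | None = None,
) -> FingerprintCube:
    """Interpolate fingerprints onto one shared grid and stack into a cube.

    Grid policy: an explicit ``grid`` wins; otherwise the grid of the sample
    named by ``reference_id``; otherwise the first fingerprint's grid. The
    shared grid is trimmed to the intersection of all sample spans — linear
    interpolation only, never extrapolation — and non-overlapping spans are a
    :class:`GridError`.
    """
    if len(fps) < 2:
        raise GridError("need at least 2 fingerprints to build a cube")
    lo = max(fp.times[0] for fp in fps)
    hi = min(fp.times[-1] for fp in fps)
    if lo > hi:
        raise GridError(f"fingerprint spans do not overlap (max start {lo} > min end {hi})")
    if grid is None:
        if reference_id is not None:
            source = next((fp for fp in fps if fp.sample_id == reference_id), None)
            if source is None:
                raise KeyError(f"reference sample {reference_id!r} not among fingerprints")
            grid = source.times
        else:
            grid = fps[0].times
    grid = np.asarray(grid, dtype=float)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        raise GridError("shared grid has fewer than 2 points inside the common span")
    values = np.empty((grid.size, 2, len(fps)))
    for j, fp in enumerate(fps):
        if fp.times.size == grid.size and np.array_equal(fp.times, grid):
            values[:, 0, j] = fp.intensities
            values[:, 1, j] = fp.masses
        else:
            values[:, 0, j] = np.interp(grid, fp.times, fp.intensities)
            values[:, 1, j] = np.interp(grid, fp.times, fp.masses)
    return FingerprintCube(time_grid=grid, sample_ids=[fp.sample_id for fp in fps], values=values)


def unfold(cube: FingerprintCube) -> UnfoldedMatrix:
    """Unfold the cube to samples x (2 x timepoints): intensity block then mass block."""
    X = np.hstack([cube.values[:, 0, :].T, cube.values[:, 1, :].T])
    return UnfoldedMatrix(X=X, sample_ids=list(cube.sample_ids), time_grid=cube.time_grid)


def fold(um: UnfoldedMatrix) -> FingerprintCube:
    """Exact inverse of :func:`unfold`."""
    t = um.n_timepoints
    values = np.empty((t, 2, um.X.shape[0]))
    values[:, 0, :] = um.X[:, :t].T
    values[:, 1, :] = um.X[:, t:].T
    return FingerprintCube(time_grid=um.time_grid, sample_ids=list(um.sample_ids), values=values)


def save_unfolded(um: UnfoldedMatrix, basepath) -> None:
    """Serialize an unfolded matrix as ``<base>.csv`` + ``<base>.meta.json`` sidecar."""
    basepath = Path(basepath)
    pd.DataFrame(um.X, index=um.sample_ids).to_csv(basepath.with_suffix(".csv"), header=False)
    meta = {
        "time_grid": um.time_grid.tolist(),
        "channels": list(CHANNELS),
        "sample_ids": list(um.sample_ids),
    }
    basepath.with_suffix(".meta.json").write_text(json.dumps(meta))


def load_unfolded(basepath) -> UnfoldedMatrix:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".meta.json").read_text())
    df = pd.read_csv(basepath.with_suffix(".csv"), header=None, index_col=0)
    if list(df.index) != meta["sample_ids"]:
        raise FormatError("unfolded CSV sample order disagrees with sidecar metadata")
    return UnfoldedMatrix(
        X=df.to_numpy(dtype=float),
        sample_ids=meta["sample_ids"],
        time_grid=np.asarray(meta["time_grid"], dtype=float),
    )
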