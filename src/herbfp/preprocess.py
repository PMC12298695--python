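"""Row- and column-wise pretreatments for unfolded fingerprint matrices.

Three families are supported, matching what is commonly explored on
chromatographic fingerprints before discriminant modeling:

* Savitzky-Golay derivatives (``sg_derivative``) — least-squares polynomial
  convolution, applied per channel block (intensity features and mass features
  separately) so the filter never runs across the channel boundary of an
  unfolded row. Edges use the interior scheme on reflected padding.
* Standard normal variate (``snv``) — per-row, per-channel-block centering and
  scaling to unit variance; removes overall loading/dilution differences.
* Autoscaling / mean centering — column statistics computed from the TRAINING
  partition only and replayed on any other partition (the no-leakage
  contract); zero-variance training columns are centered and left unscaled.

A :class:`PreprocessSpec` is an ordered list of such steps, restricted so that
the single column-statistics step (autoscale or mean_center), if present,
comes last. The spec plus its fitted state serialize into the model file so
prediction replays the exact pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateRowError, ParameterError

_ROWWISE = {"sg_derivative", "snv"}
_COLUMNWISE = {"autoscale", "mean_center"}


def sg_derivative(rows: np.ndarray, window: int = 15, polyorder: int = 2,
                  deriv_order: int = 1) -> np.ndarray:
    """Savitzky-Golay derivative along the last axis.

    Exactly reproduces derivatives of polynomials up to ``polyorder`` at
    interior points; edges are handled by reflecting the signal.
    """
    if window % 2 == 0 or window <= polyorder or polyorder < deriv_order:
        raise ParameterError(
            f"need odd window > polyorder >= deriv_order, got "
            f"window={window}, polyorder={polyorder}, deriv={deriv_order}"
        )
    rows = np.asarray(rows, dtype=float)
    if rows.shape[-1] < window:
        raise ParameterError(f"signal of length {rows.shape[-1]} shorter than window {window}")
    return savgol_filter(rows, window, polyorder, deriv=deriv_order, mode="mirror", axis=-1)


def snv(rows: np.ndarray, sample_ids=None) -> np.ndarray:
    """Standard normal variate: (row - mean) / sd per row (sd with ddof=1)."""
    rows = np.asarray(rows, dtype=float)
    one_dim = rows.ndim == 1
    rows = np.atleast_2d(rows)
    mean = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if flat.size:
        i = int(flat[0])
        name = sample_ids[i] if sample_ids is not None else f"row {i}"
        raise DegenerateRowError(f"SNV undefined for constant row ({name})")
    out = (rows - mean) / sd
    return out[0] if one_dim else out


@dataclass
class ColumnScaler:
    """Column centering/scaling fitted on training rows and replayed elsewhere."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, train: np.ndarray, with_scaling: bool) -> "ColumnScaler":
        train = np.asarray(train, dtype=float)
        mean = train.mean(axis=0)
        if with_scaling:
            scale = train.std(axis=0, ddof=0)
            scale[scale == 0.0] = 1.0  # zero-variance columns: center only
        else:
            scale = np.ones(train.shape[1])
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def autoscale_fit_apply(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, ColumnScaler]:
    """Autoscale both partitions using TRAIN column statistics only."""
    scaler = ColumnScaler.fit(train, with_scaling=True)
    return scaler.transform(train), scaler.transform(test), scaler


@dataclass
class PreprocessSpec:
    """Ordered pretreatment recipe applied to unfolded rows.

    ``steps`` entries are dicts with a ``name`` key: ``sg_derivative`` (params
    window/polyorder/deriv_order), ``snv``, ``autoscale``, ``mean_center``.
    """

    steps: list[dict] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        col_steps = [i for i, s in enumerate(self.steps) if s["name"] in _COLUMNWISE]
        if len(col_steps) > 1:
            raise ParameterError("autoscale/mean_center may appear at most once")
        if col_steps and col_steps[0] != len(self.steps) - 1:
            raise ParameterError("the column-statistics step must come last")
        for s in self.steps:
            if s["name"] not in _ROWWISE | _COLUMNWISE:
                raise ParameterError(f"unknown preprocessing step {s['name']!r}")
            if s["name"] == "sg_derivative":
                w, p, d = s.get("window", 15), s.get("polyorder", 2), s.get("deriv_order", 1)
                if w % 2 == 0 or w <= p or p < d:
                    raise ParameterError(f"invalid SG parameters {s}")

    # -- row-wise part (stateless, safe to apply before any split) ----------

    def apply_rowwise(self, X: np.ndarray, n_time: int | None = None, sample_ids=None) -> np.ndarray:
        """Apply the stateless row-wise steps; ``n_time`` splits the row into
        its intensity and mass channel blocks."""
        X = np.asarray(X, dtype=float)
        blocks = self._blocks(X.shape[-1], n_time)
        block_names = ["intensity", "mass"] if len(blocks) == 2 else ["all"]
        for s in self.steps:
            if s["name"] == "sg_derivative":
                chan = s.get("channel", "all")
                X = np.concatenate(
                    [sg_derivative(X[..., a:b], s.get("window", 15), s.get("polyorder", 2),
                                   s.get("deriv_order", 1))
                     if chan in ("all", name) or len(blocks) == 1 else X[..., a:b]
                     for name, (a, b) in zip(block_names, blocks)], axis=-1)
            elif s["name"] == "snv":
                X = np.concatenate([snv(X[..., a:b], sample_ids) for a, b in blocks], axis=-1)
        return X

    @staticmethod
    def _blocks(n_features: int, n_time: int | None) -> list[tuple[int, int]]:
        if n_time is None or 2 * n_time != n_features:
            return [(0, n_features)]
        return [(0, n_time), (n_time, 2 * n_time)]

    # -- column-wise part (fitted on training rows only) --------------------

    def fit_scaler(self, train_rowwise: np.ndarray) -> ColumnScaler | None:
        for s in self.steps:
            if s["name"] == "autoscale":
                return ColumnScaler.fit(train_rowwise, with_scaling=True)
            if s["name"] == "mean_center":
                return ColumnScaler.fit(train_rowwise, with_scaling=False)
        return None

    def to_dict(self) -> dict:
        return {"steps": [dict(s) for s in self.steps], "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(steps=[dict(s) for s in d["steps"]], label=d.get("label", ""))


#: Named recipes mirroring the pretreatments usually tabulated in model reports.
SPEC_REGISTRY: dict[str, PreprocessSpec] = {
    "none": PreprocessSpec(steps=[{"name": "mean_center"}], label="-"),
    "sg1": PreprocessSpec(
        steps=[{"name": "sg_derivative", "window": 15, "polyorder": 2, "deriv_order": 1},
               {"name": "mean_center"}],
        label="1st derivative",
    ),
    "sg1-intensity": PreprocessSpec(
        steps=[{"name": "sg_derivative", "window": 15, "polyorder": 2, "deriv_order": 1,
                "channel": "intensity"},
               {"name": "mean_center"}],
        label="1st derivative (intensity)",
    ),
    "sg2": PreprocessSpec(
        steps=[{"name": "sg_derivative", "window": 15, "polyorder": 3, "deriv_order": 2},
               {"name": "mean_center"}],
        label="2nd derivative",
    ),
    "snv": PreprocessSpec(steps=[{"name": "snv"}, {"name": "mean_center"}], label="SNV"),
    "autoscale": PreprocessSpec(steps=[{"name": "autoscale"}], label="autoscaling"),
    "sg1+autoscale": PreprocessSpec(
        steps=[{"name": "sg_derivative", "window": 15, "polyorder": 2, "deriv_order": 1},
               {"name": "autoscale"}],
        label="1st derivative + autoscaling",
    ),
}


def resolve_spec(spec) -> PreprocessSpec:
    """Accept a PreprocessSpec, a registry key, or a dict."""
    if isinstance(spec, PreprocessSpec):
        return spec
    if isinstance(spec, str):
        try:
            return SPEC_REGISTRY[spec]
        except KeyError:
            raise ParameterError(
                f"unknown preprocessing recipe {spec!r}; known: {sorted(SPEC_REGISTRY)}"
            ) from None
    if isinstance(spec, dict):
        return PreprocessSpec.from_dict(spec)
    raise ParameterError(f"cannot interpret preprocessing spec {spec!r}")
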