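"""Correlation optimized warping (COW) of chromatographic fingerprints.

COW removes retention-time shifts between runs by piecewise-linear warping.
The reference signal is cut into segments of a nominal length; the warped
signal's segment boundaries may each move by at most ``slack`` points relative
to the previous boundary's displacement (so displacement accumulates along the
run but never jumps), and the warp maximizing the summed Pearson correlation
between linearly interpolated sample segments and their reference segments is
found exactly by dynamic programming over boundary positions.

Conventions:

* the first and last boundary are pinned to the signal ends (endpoints are
  preserved, no time reversal is representable);
* the last segment absorbs the remainder when the length is not divisible by
  the segment length;
* a zero-variance segment contributes correlation 0 (flat baseline stretches
  must not poison the optimisation);
* the mass channel of a cube is never warped independently — it follows the
  node trajectory fitted on the intensity channel, preserving the per-scan
  (intensity, mass) pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import FingerprintCube
from .errors import ParameterError

_NEG_INF = -np.inf


@dataclass(frozen=True)
class CowParams:
    """Warp parameters: nominal segment length and boundary slack, in points."""

    segment_length: int
    slack: int
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.slack < 1:
            raise ParameterError(f"slack must be >= 1, got {self.slack}")
        if self.segment_length < self.slack + 3:
            raise ParameterError(
                f"segment_length must be >= slack + 3, got {self.segment_length} "
                f"with slack {self.slack}"
            )


@dataclass
class WarpResult:
    """Optimal warp of one sample onto the reference grid."""

    aligned: np.ndarray  # warped intensity on the reference grid
    node_positions: np.ndarray  # boundary indices in the sample, strictly increasing
    ref_boundaries: np.ndarray  # fixed boundary indices on the reference grid
    score: float  # sum of per-segment correlations, <= n_segments

    @property
    def n_segments(self) -> int:
        return self.ref_boundaries.size - 1


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention corr = 0."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((a @ b) / (na * nb))


def _boundaries(length: int, segment_length: int) -> np.ndarray:
    n_seg = (length - 1) // segment_length
    bounds = np.arange(n_seg) * segment_length
    return np.append(bounds, length - 1)


def _offset_range(i: int, n_seg: int, slack: int) -> np.ndarray:
    # reachable from 0 in i steps and back to 0 in the remaining n_seg - i steps
    r = slack * min(i, n_seg - i)
    return np.arange(-r, r + 1)


def _interp_segments(sample: np.ndarray, starts: np.ndarray, ends: np.ndarray, n_out: int) -> np.ndarray:
    """Linearly resample sample[start..end] (inclusive) to n_out points for every
    broadcast (start, end) pair; output shape is broadcast(starts, ends) + (n_out,)."""
    frac = np.linspace(0.0, 1.0, n_out)
    pos = starts[..., None] + (ends[..., None] - starts[..., None]) * frac
    i0 = np.floor(pos).astype(np.intp)
    np.clip(i0, 0, sample.size - 2, out=i0)
    w = pos - i0
    return sample[i0] * (1.0 - w) + sample[i0 + 1] * w


def _corr_against(ref_seg: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row-block of ``segs`` (..., n) with ref_seg."""
    r = ref_seg - ref_seg.mean()
    nr = np.sqrt(r @ r)
    s = segs - segs.mean(axis=-1, keepdims=True)
    ns = np.sqrt(np.einsum("...i,...i->...", s, s))
    num = s @ r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / (ns * nr)
    out[~np.isfinite(out)] = 0.0
    if nr == 0.0:
        out[...] = 0.0
    return out


def cow_align(sample: np.ndarray, reference: np.ndarray, params: CowParams) -> WarpResult:
    """Warp ``sample`` onto ``reference`` by COW; exact optimum via dynamic programming.

    Both signals must be at least two segments long. The sample may have a
    different length from the reference; boundary displacements are measured
    against the proportionally placed nominal boundaries in the sample.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    seg, slack = params.segment_length, params.slack
    if len(reference) < 2 * seg or len(sample) < 2 * seg:
        raise ParameterError(
            f"signals of length {len(sample)}/{len(reference)} are too short for "
            f"two segments of {seg} points"
        )
    ref_b = _boundaries(len(reference), seg)
    n_seg = ref_b.size - 1
    # nominal boundaries in the sample, proportional when lengths differ
    nominal = np.round(ref_b * (len(sample) - 1) / (len(reference) - 1)).astype(np.intp)

    offsets = [_offset_range(i, n_seg, slack) for i in range(n_seg + 1)]
    scores = [np.full(o.size, _NEG_INF) for o in offsets]
    back: list[np.ndarray] = [np.zeros(o.size, dtype=np.intp) for o in offsets]
    scores[0][0] = 0.0
    deltas = np.arange(-slack, slack + 1)
    for i in range(1, n_seg + 1):
        off_prev, off_cur = offsets[i - 1], offsets[i]
        ref_seg = reference[ref_b[i - 1] : ref_b[i] + 1]
        # only transitions changing the displacement by at most `slack` are
        # admissible, so correlations are computed for those pairs alone
        d_prev = off_cur[:, None] - deltas[None, :]  # (n_end, n_delta)
        valid = (d_prev >= off_prev[0]) & (d_prev <= off_prev[-1])
        starts = (nominal[i - 1] + np.clip(d_prev, off_prev[0], off_prev[-1])).astype(float)
        ends = np.broadcast_to((nominal[i] + off_cur)[:, None], d_prev.shape).astype(float)
        table = _corr_against(ref_seg, _interp_segments(sample, starts, ends, ref_seg.size))
        prev_idx = np.clip(d_prev - off_prev[0], 0, off_prev.size - 1)
        cand = np.where(valid, scores[i - 1][prev_idx] + table, _NEG_INF)
        kbest = np.argmax(cand, axis=1)
        rows = np.arange(off_cur.size)
        back[i] = prev_idx[rows, kbest]
        scores[i] = cand[rows, kbest]
    # backtrack from the pinned final boundary (offset 0)
    j = int(np.flatnonzero(offsets[n_seg] == 0)[0])
    final_score = float(scores[n_seg][j])
    node = np.empty(n_seg + 1, dtype=np.intp)
    for i in range(n_seg, -1, -1):
        node[i] = nominal[i] + offsets[i][j]
        if i > 0:
            j = int(back[i][j])
    aligned = apply_warp(sample, node, ref_b, len(reference))
    return WarpResult(aligned=aligned, node_positions=node, ref_boundaries=ref_b,
                      score=final_score)


def apply_warp(signal: np.ndarray, node_positions: np.ndarray, ref_boundaries: np.ndarray,
               out_length: int) -> np.ndarray:
    """Apply a fitted node trajectory to any channel of the same sample."""
    signal = np.asarray(signal, dtype=float)
    pos = np.empty(out_length)
    for k in range(ref_boundaries.size - 1):
        r0, r1 = ref_boundaries[k], ref_boundaries[k + 1]
        b0, b1 = node_positions[k], node_positions[k + 1]
        u = np.arange(r0, r1 + 1)
        pos[r0 : r1 + 1] = b0 + (u - r0) * (b1 - b0) / (r1 - r0)
    return np.interp(pos, np.arange(signal.size), signal)


def cow_grid_search(
    samples: np.ndarray,
    reference: np.ndarray,
    segment_grid=(30, 50, 75, 100),
    slack_grid=(1, 2, 3, 5),
) -> tuple[CowParams, list[WarpResult]]:
    """Try every (segment, slack) pair; keep the one maximizing the mean
    correlation of the aligned samples with the reference.

    Pairs violating segment >= slack + 3 are skipped. Ties break toward the
    smaller slack, then the smaller segment, so an already-aligned set returns
    the least aggressive warp.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if len(segment_grid) == 0 or len(slack_grid) == 0:
        raise ParameterError("segment and slack grids must be non-empty")
    combos = sorted(
        ((sl, seg) for sl in slack_grid for seg in segment_grid if seg >= sl + 3)
    )
    if not combos:
        raise ParameterError("no admissible (segment, slack) pair in the grids")
    best: tuple[float, CowParams, list[WarpResult]] | None = None
    for sl, seg in combos:
        params = CowParams(segment_length=seg, slack=sl)
        results = [cow_align(s, reference, params) for s in samples]
        mean_corr = float(np.mean([pearson(r.aligned, reference) for r in results]))
        if best is None or mean_corr > best[0] + 1e-12:
            best = (mean_corr, params, results)
    return best[1], best[2]


def estimate_shift(sample: np.ndarray, reference: np.ndarray, max_lag: int) -> float:
    """Lag (in points, fractional) maximizing the overlap-normalized
    cross-correlation, refined to sub-sample precision by parabolic
    interpolation of the correlation peak.

    Positive lag means the sample runs late relative to the reference. Ties
    break toward the smaller |lag|.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    s = sample - sample.mean()
    r = reference - reference.mean()

    def _val(lag: int) -> float:
        if lag >= 0:
            a, b = s[lag:], r[: r.size - lag]
        else:
            a, b = s[: s.size + lag], r[-lag:]
        n = min(a.size, b.size)
        if n < 2:
            return -np.inf
        return float(a[:n] @ b[:n]) / n

    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.array([_val(int(lag)) for lag in lags])
    order = np.lexsort((np.abs(lags), -vals))  # max value, then smallest |lag|
    k = int(order[0])
    lag = float(lags[k])
    if 0 < k < lags.size - 1 and np.isfinite(vals[k - 1]) and np.isfinite(vals[k + 1]):
        denom = vals[k - 1] - 2 * vals[k] + vals[k + 1]
        if denom < 0:  # proper maximum: refine within +/- half a point
            delta = 0.5 * (vals[k - 1] - vals[k + 1]) / denom
            lag += float(np.clip(delta, -0.5, 0.5))
    return lag


def apply_shift(signal: np.ndarray, lag: float) -> np.ndarray:
    """Advance a channel by ``lag`` points, fractional lags via linear
    interpolation (edge values clamped)."""
    signal = np.asarray(signal, dtype=float)
    idx = np.arange(signal.size, dtype=float)
    return np.interp(np.clip(idx + lag, 0, signal.size - 1), idx, signal)


def align_channels(
    intensity: np.ndarray,
    mass: np.ndarray,
    reference: np.ndarray,
    params: CowParams,
    preshift_max: int = 0,
) -> tuple[np.ndarray, np.ndarray, WarpResult, int]:
    """Two-stage alignment of one sample's channel pair onto a reference trace.

    A coarse global lag (bounded by ``preshift_max`` points; 0 disables the
    stage) absorbs run-level retention shifts, then COW corrects the residual
    local drift. The mass channel follows the intensity warp exactly.
    """
    lag = 0
    if preshift_max > 0:
        lag = estimate_shift(intensity, reference, preshift_max)
        if lag != 0:
            intensity = apply_shift(intensity, lag)
            mass = apply_shift(mass, lag)
    warp = cow_align(intensity, reference, params)
    mass_aligned = apply_warp(mass, warp.node_positions, warp.ref_boundaries, reference.size)
    return warp.aligned, mass_aligned, warp, lag


def most_representative_reference(cube: FingerprintCube) -> str:
    """Alternative reference policy: the sample whose intensity trace has the
    highest mean correlation to all others."""
    X = cube.values[:, 0, :].T  # samples x time
    n = X.shape[0]
    corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    mean_to_others = (corr.sum(axis=1) - 1.0) / (n - 1)
    return cube.sample_ids[int(np.argmax(mean_to_others))]


def align_cube(cube: FingerprintCube, params: CowParams, preshift_max: int = 0) -> FingerprintCube:
    """Warp every sample's intensity trace onto the designated reference sample;
    the mass channel follows the same node trajectory.

    ``preshift_max`` > 0 enables the coarse global-lag stage of
    :func:`align_channels` before each warp.
    """
    if params.reference_id is None:
        raise ParameterError("CowParams.reference_id must name the reference sample")
    ref_idx = cube.sample_index(params.reference_id)  # raises KeyError when absent
    reference = cube.values[:, 0, ref_idx]
    values = cube.values.copy()
    for j in range(len(cube.sample_ids)):
        if j == ref_idx:
            continue  # identity warp, keep exactly
        intensity, mass, _, _ = align_channels(
            cube.values[:, 0, j], cube.values[:, 1, j], reference, params, preshift_max
        )
        values[:, 0, j] = intensity
        values[:, 1, j] = mass
    return FingerprintCube(time_grid=cube.time_grid.copy(), sample_ids=list(cube.sample_ids),
                           values=values)
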