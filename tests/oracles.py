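"""Independent brute-force oracles used to pin down the optimisation code.

These deliberately re-derive results from first principles (exhaustive
enumeration, closed-form least squares) without touching the implementation
paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def _pearson0(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def brute_force_cow(sample: np.ndarray, reference: np.ndarray, segment_length: int,
                    slack: int) -> float:
    """Exhaustive enumeration of every admissible warp; returns the best score.

    Boundary displacements d_i are integers with d_0 = d_N = 0,
    |d_i - d_{i-1}| <= slack and |d_i| <= slack * min(i, N - i); segments are
    linearly resampled to the reference segment length and scored by Pearson
    correlation (zero-variance convention: 0).
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    L = reference.size
    n_seg = (L - 1) // segment_length
    ref_b = np.append(np.arange(n_seg) * segment_length, L - 1)
    nominal = np.round(ref_b * (sample.size - 1) / (L - 1)).astype(int)

    ranges = []
    for i in range(1, n_seg):
        r = slack * min(i, n_seg - i)
        ranges.append(range(-r, r + 1))
    best = -np.inf
    for interior in itertools.product(*ranges):
        d = (0,) + interior + (0,)
        if any(abs(d[i] - d[i - 1]) > slack for i in range(1, n_seg + 1)):
            continue
        total = 0.0
        for i in range(1, n_seg + 1):
            b0, b1 = nominal[i - 1] + d[i - 1], nominal[i] + d[i]
            ref_seg = reference[ref_b[i - 1]: ref_b[i] + 1]
            pos = np.linspace(b0, b1, ref_seg.size)
            seg = np.interp(pos, np.arange(sample.size), sample)
            total += _pearson0(seg, ref_seg)
        best = max(best, total)
    return best


def ols_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares training predictions with intercept, via lstsq."""
    Xa = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return Xa @ beta
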