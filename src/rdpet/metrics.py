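"""Evaluation metrics and convergence detection for reconstruction runs.

The convergence marker used throughout is whole-object NRMSE against a
converged reference falling (and staying) below a threshold, default 0.01.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["nrmse", "voi_aem", "convergence_update"]


def nrmse(
    x: np.ndarray, x_ref: np.ndarray, mask: np.ndarray, norm_value: float
) -> float:
    """Root-mean-square error over ``mask``, divided by ``norm_value``
    (the activity of the largest background region of the phantom)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be nonempty")
    if norm_value <= 0:
        raise ValueError("norm_value must be > 0")
    diff = np.asarray(x, dtype=float)[mask] - np.asarray(x_ref, dtype=float)[mask]
    return float(np.sqrt(np.mean(diff * diff)) / norm_value)


def voi_aem(
    x: np.ndarray, x_ref: np.ndarray, voi_mask: np.ndarray, norm_value: float
) -> float:
    """Absolute error of the volume-of-interest mean, normalized:
    |mean_VOI(x) - mean_VOI(x_ref)| / norm_value."""
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if not voi_mask.any():
        raise ValueError("VOI mask must be nonempty")
    if norm_value <= 0:
        raise ValueError("norm_value must be > 0")
    return float(
        abs(np.asarray(x, float)[voi_mask].mean() - np.asarray(x_ref, float)[voi_mask].mean())
        / norm_value
    )


def convergence_update(
    history: Sequence[float] | Sequence[Sequence[float]] | np.ndarray,
    threshold: float = 0.01,
) -> int | None:
    """First index where every tracked metric is below ``threshold`` and
    stays below it for all later recorded points; None if never attained.

    ``history`` is a 1-D series of one metric or a 2-D array of shape
    (n_points, n_metrics).
    """
    arr = np.asarray(history, dtype=float)
    if arr.size == 0:
        raise ValueError("history must be nonempty")
    if arr.ndim == 1:
        arr = arr[:, None]
    below = np.all(arr < threshold, axis=1)
    # sustained: suffix of all-below points
    idx = None
    for t in range(len(below) - 1, -1, -1):
        if below[t]:
            idx = t
        else:
            break
    return idx
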