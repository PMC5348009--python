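"""Sorted, stretched, upsampled and smoothed trial x time images.

To compare trial-by-trial structure across subjects with different numbers
of kept trials, each subject's trial x time matrix (button-press consistency
or signed OKN velocity) is sorted by mean consistency over the 2-s trial
(descending), linearly stretched along the trial dimension to a common 1000
rows, smoothed along rows only with a 31-point boxcar, and averaged across
subjects.  Velocity rows of leftward trials have their sign flipped before
imaging so that "following the percept" is positive everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .button_press import ConsistencyTrace

__all__ = [
    "N_IMAGE_ROWS",
    "ROW_SMOOTH_POINTS",
    "TrialImage",
    "sort_trials",
    "stretch_upsample",
    "smooth_rows",
    "average_images",
    "build_subject_image",
]

N_IMAGE_ROWS = 1000
ROW_SMOOTH_POINTS = 31


@dataclass
class TrialImage:
    """Normalised-trial x time image; rows span best-to-worst trials."""

    values: np.ndarray  # (n_rows, n_times)
    time_s: np.ndarray


def sort_trials(
    matrix: np.ndarray, consistencies: Sequence[ConsistencyTrace] | np.ndarray
) -> np.ndarray:
    """Rows of ``matrix`` in stable descending order of mean consistency.

    ``consistencies`` is either one ConsistencyTrace per row or a precomputed
    vector of per-trial mean-consistency keys.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 1:
        raise ValueError("need at least one trial")
    if isinstance(consistencies, np.ndarray) and consistencies.ndim == 1:
        keys = consistencies.astype(float)
    else:
        keys = np.array([float(np.mean(c.c)) for c in consistencies])
    if keys.shape[0] != matrix.shape[0]:
        raise ValueError("one sort key per trial required")
    order = np.argsort(-keys, kind="stable")
    return matrix[order]


def stretch_upsample(image: np.ndarray, n_rows: int = N_IMAGE_ROWS) -> np.ndarray:
    """Linearly interpolate the trial dimension onto ``n_rows`` positions
    spanning the first to the last trial (endpoints included)."""
    image = np.asarray(image, dtype=float)
    n_trials = image.shape[0]
    if n_trials == 1:
        warnings.warn("single trial: replicating the row", stacklevel=2)
        return np.repeat(image, n_rows, axis=0)
    src = np.linspace(0.0, 1.0, n_trials)
    dst = np.linspace(0.0, 1.0, n_rows)
    out = np.empty((n_rows, image.shape[1]))
    for j in range(image.shape[1]):
        out[:, j] = np.interp(dst, src, image[:, j])
    return out


def smooth_rows(image: np.ndarray, k: int = ROW_SMOOTH_POINTS) -> np.ndarray:
    """Centred k-point moving average along the trial dimension only
    (never across time), truncated and renormalised at the edges."""
    if k % 2 == 0:
        raise ValueError("kernel length k must be odd")
    image = np.asarray(image, dtype=float)
    kernel = np.ones(k)
    num = np.apply_along_axis(lambda col: np.convolve(col, kernel, "same"), 0, image)
    den = np.convolve(np.ones(image.shape[0]), kernel, "same")
    return num / den[:, None]


def average_images(images: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of equally shaped subject images."""
    images = [np.asarray(im, dtype=float) for im in images]
    if not images:
        raise ValueError("no images to average")
    shape = images[0].shape
    for im in images[1:]:
        if im.shape != shape:
            raise ValueError(f"shape mismatch: {im.shape} vs {shape}")
    return np.mean(np.stack(images), axis=0)


def build_subject_image(
    matrix: np.ndarray,
    sort_keys: np.ndarray,
    time_s: np.ndarray,
    stim_dirs: np.ndarray | None = None,
    n_rows: int = N_IMAGE_ROWS,
    k: int = ROW_SMOOTH_POINTS,
) -> TrialImage:
    """Full per-subject chain: (flip leftward rows) -> sort -> stretch ->
    smooth.  ``stim_dirs`` (per-trial -1/+1) triggers the sign flip used for
    velocity images; omit it for consistency images."""
    matrix = np.asarray(matrix, dtype=float)
    if stim_dirs is not None:
        matrix = matrix * np.asarray(stim_dirs, dtype=float)[:, None]
    ordered = sort_trials(matrix, np.asarray(sort_keys, dtype=float))
    return TrialImage(
        values=smooth_rows(stretch_upsample(ordered, n_rows), k),
        time_s=np.asarray(time_s, dtype=float),
    )
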