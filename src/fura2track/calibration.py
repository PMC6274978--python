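"""Window-size calibration from user-selected cell ROI areas.

The processing window side ``w`` used by filtering, thresholding and ROI
extraction is derived from the mean area of a handful of user-selected cell
ROIs: w = round(a * sqrt(mean_area)), on the assumption that cells are
bounded by w x w squares.  The scale factor ``a`` defaults to 2, the value
that minimises the mask MSE against expert ground-truth segmentations; this
module also provides that grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_ratio import InputError

DEFAULT_A = 2.0
DEFAULT_KT = 1.0
DEFAULT_OPEN_RADIUS = 3
DEFAULT_DILATE_RADIUS = 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SegmentationParams:
    """Calibrated segmentation parameters.

    Parameters
    ----------
    w : int
        Processing window side in pixels (>= 3); also the ROI side used for
        CP extraction and half of it gates the tracking fallback.
    a : float
        Scale factor relating mean cell area to ``w`` (default 2).
    k_T : float
        Niblack threshold gain (default 1).
    open_radius, dilate_radius : int
        Structuring-disk radii for the binary conditioning stage.
    """

    w: int
    a: float = DEFAULT_A
    k_T: float = DEFAULT_KT
    open_radius: int = DEFAULT_OPEN_RADIUS
    dilate_radius: int = DEFAULT_DILATE_RADIUS

    def __post_init__(self) -> None:
        if self.w < 3:
            raise InputError(f"window side w must be >= 3, got {self.w}")
        if self.a <= 0:
            raise InputError("scale factor a must be positive")

    @property
    def w_median(self) -> int:
        """Median-filter window side, w/8 rounded, at least 1."""
        return max(1, _round_half_up(self.w / 8))

    @classmethod
    def from_areas(cls, roi_areas: Sequence[float], a: float = DEFAULT_A, **kw) -> "SegmentationParams":
        return cls(w=compute_window_size(roi_areas, a), a=a, **kw)


def compute_window_size(roi_areas: Sequence[float], a: float = DEFAULT_A) -> int:
    """Window side w = round(a * sqrt(mean ROI area)), clamped to >= 3.

    More selected ROIs give a better estimate of the mean cell area; the
    formula itself does not change with the count.
    """
    areas = np.asarray(list(roi_areas), dtype=float)
    if areas.size == 0:
        raise InputError("need at least one ROI area")
    if np.any(areas <= 0):
        raise InputError("ROI areas must be positive")
    if a <= 0:
        raise InputError("scale factor a must be positive")
    return max(3, _round_half_up(a * math.sqrt(areas.mean())))


def mask_mse(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mean square error between two binary masks taken as 0/1 reals.

    Symmetric, in [0, 1]; equals the fraction of disagreeing pixels.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise InputError(f"mask dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a.astype(float) - b.astype(float)) ** 2))


def calibrate_a(
    ground_truth_masks: Sequence[np.ndarray],
    raw_frames: Sequence[np.ndarray],
    roi_areas: Sequence[float],
    a_grid: Iterable[float],
) -> Tuple[float, pd.DataFrame]:
    """Grid-search the scale factor ``a`` against ground-truth masks.

    For each candidate ``a`` the full segmentation pipeline is run on every
    raw frame with the window size implied by that ``a``, and the mean mask
    MSE against the paired ground-truth masks is recorded.  Returns the
    arg-min ``a`` (ties toward smaller ``a``) and the (a, mse) curve.
    """
    from .segmentation import segment_frame  # deferred: calibration drives segmentation

    masks = list(ground_truth_masks)
    frames = list(raw_frames)
    grid = sorted(set(float(a) for a in a_grid))
    if len(masks) != len(frames):
        raise InputError("ground-truth masks and raw frames must pair one-to-one")
    if not masks:
        raise InputError("need at least one ground-truth mask")
    if not grid:
        raise InputError("a_grid must be nonempty")

    rows: List[dict] = []
    for a in grid:
        params = SegmentationParams.from_areas(roi_areas, a=a)
        errs = [
            mask_mse(segment_frame(frame, params).binary, gt)
            for frame, gt in zip(frames, masks)
        ]
        rows.append({"a": a, "mse": float(np.mean(errs))})
    curve = pd.DataFrame(rows)
    best = float(curve.loc[curve["mse"].idxmin(), "a"])  # idxmin: first == smallest a
    return best, curve
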