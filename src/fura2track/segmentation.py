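"""Adaptive segmentation of 340-nm frames into labeled cell blobs.

Per-frame pipeline: median filter (window w/8) -> linear histogram stretch
-> Niblack local thresholding T(x,y) = m(x,y) + k_T * s(x,y) computed with
integral images -> binary conditioning (opening, hole fill, dilation) ->
8-connected component labeling with centroids and areas.

Conventions (used consistently by tracking and the Kalman state): pixel
centers at integer coordinates, x = column, y = row, origin top-left,
0-based.  Local-statistics windows are cropped at image borders — the mean
and standard deviation are taken over the valid intersection of the w x w
window with the image, which avoids padding artifacts inflating s near
edges.  The foreground test is strict (I > T), so a perfectly uniform image
segments to all background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .calibration import SegmentationParams
from .io_ratio import FrameSequence, Channel, InputError

__all__ = [
    "LabeledFrame",
    "preprocess",
    "local_mean_std",
    "niblack_threshold",
    "condition_binary",
    "label_components",
    "segment_frame",
    "segment_sequence",
]


@dataclass
class LabeledFrame:
    """Binary mask plus connected-component labels of one frame.

    ``labels`` is nonzero exactly where ``binary`` is true; components are
    the 8-connected blobs, labeled 1..L in raster-scan order of their first
    pixel.  ``centroids`` holds (x, y) per label (row ``lab - 1``) as
    unweighted pixel-coordinate means; ``areas`` the pixel counts.
    """

    binary: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray  # (L, 2) float, columns (x, y)
    areas: np.ndarray  # (L,) int

    @property
    def n_components(self) -> int:
        return len(self.areas)

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def centroid(self, label: int) -> Tuple[float, float]:
        x, y = self.centroids[label - 1]
        return float(x), float(y)


def preprocess(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Median filter then linear histogram stretch onto [0, 255].

    Operates on (a copy of) a raw EX340 frame; never the ratio source.  A
    constant frame passes through unchanged (the stretch would be 0/0).
    The stretched image is re-quantized to the 0-255 integer scale
    (round-half-up) — all stages work on that scale, and integer pixel
    values keep the integral-image window sums exact so that perfectly
    uniform regions threshold unambiguously to background.
    """
    frame = np.asarray(frame, dtype=np.uint8)
    if params.w_median > 1:
        filtered = ndimage.median_filter(frame, size=params.w_median, mode="reflect")
    else:
        filtered = frame.copy()
    lo, hi = int(filtered.min()), int(filtered.max())
    if hi == lo:
        return filtered
    stretched = (filtered.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.floor(stretched + 0.5).astype(np.uint8)


def local_mean_std(frame: np.ndarray, w: int) -> Tuple[np.ndarray, np.ndarray]:
    """Windowed mean and population std via integral images.

    The w x w window centered at each pixel is cropped to the image, so
    statistics near borders are over the valid intersection only.  Sums of
    I and I^2 are exact in float64 for 8-bit input; the std uses
    s = sqrt(E[I^2] - E[I]^2) with negative round-off clamped at 0.
    """
    img = np.asarray(frame, dtype=np.float64)
    m_rows, n_cols = img.shape
    if w < 3:
        raise InputError(f"window side must be >= 3, got {w}")
    if w > m_rows and w > n_cols:
        raise InputError(f"window side {w} exceeds both image dimensions {img.shape}")

    # integral images with a zero top/left border row
    ii = np.zeros((m_rows + 1, n_cols + 1))
    ii2 = np.zeros((m_rows + 1, n_cols + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=ii[1:, 1:])
    np.cumsum(np.cumsum(img * img, axis=0), axis=1, out=ii2[1:, 1:])

    half_lo = (w - 1) // 2  # pixels above/left of center
    half_hi = w // 2  # pixels below/right of center
    rows = np.arange(m_rows)
    cols = np.arange(n_cols)
    r0 = np.clip(rows - half_lo, 0, m_rows)[:, None]
    r1 = np.clip(rows + half_hi + 1, 0, m_rows)[:, None]
    c0 = np.clip(cols - half_lo, 0, n_cols)[None, :]
    c1 = np.clip(cols + half_hi + 1, 0, n_cols)[None, :]

    def window_sum(tab: np.ndarray) -> np.ndarray:
        return tab[r1, c1] - tab[r0, c1] - tab[r1, c0] + tab[r0, c0]

    count = (r1 - r0) * (c1 - c0)
    mean = window_sum(ii) / count
    var = window_sum(ii2) / count - mean * mean
    std = np.sqrt(np.clip(var, 0.0, None))
    return mean, std


def niblack_threshold(frame: np.ndarray, w: int, k_T: float = 1.0) -> np.ndarray:
    """Niblack adaptive binarization: foreground iff I > m + k_T * s."""
    img = np.asarray(frame, dtype=np.float64)
    mean, std = local_mean_std(img, w)
    return img > mean + k_T * std


def condition_binary(binary: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Morphological conditioning: opening, hole fill, dilation, in order.

    Opening uses a disk of ``open_radius``; holes are background regions
    not 4-connected to the image border; the final dilation uses a disk of
    ``dilate_radius``.
    """
    mask = np.asarray(binary, dtype=bool)
    if params.open_radius > 0:
        mask = morphology.opening(mask, morphology.disk(params.open_radius))
    mask = ndimage.binary_fill_holes(mask)  # default cross structure = 4-connected bg
    if params.dilate_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(params.dilate_radius))
    return mask


def label_components(binary: np.ndarray) -> LabeledFrame:
    """8-connected component labeling with centroids and areas."""
    mask = np.asarray(binary, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    centroids = np.zeros((n, 2))
    areas = np.zeros(n, dtype=int)
    if n:
        # ndimage.center_of_mass returns (row, col) == (y, x)
        com = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
        com = np.atleast_2d(com)
        centroids[:, 0] = com[:, 1]
        centroids[:, 1] = com[:, 0]
        areas[:] = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    return LabeledFrame(binary=mask, labels=labels, centroids=centroids, areas=areas)


def segment_frame(frame: np.ndarray, params: SegmentationParams) -> LabeledFrame:
    """Full single-frame pipeline: preprocess -> threshold -> condition -> label."""
    pre = preprocess(frame, params)
    raw_mask = niblack_threshold(pre, params.w, params.k_T)
    mask = condition_binary(raw_mask, params)
    return label_components(mask)


def segment_sequence(seq: FrameSequence, params: SegmentationParams) -> List[LabeledFrame]:
    """Segment every frame of an EX340 sequence independently."""
    if seq.channel is not Channel.EX340:
        raise InputError("segmentation runs on the EX340 sequence")
    return [segment_frame(seq.frames[i], params) for i in range(seq.n_frames)]
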