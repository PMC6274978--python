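"""Image-sequence I/O and ratiometric preprocessing.

Fura-2 experiments produce two single-channel 8-bit TIFF sequences, one per
excitation wavelength (340 nm and 380 nm), with emission read at 510 nm.
The pixelwise 340/380 quotient ("ratio image") is the quantity that reports
intracellular Ca2+: calcium profiles (CPs) are mean ratio intensities inside
a cell's ROI over time.

This module loads raw sequences, builds the ratio sequence, and writes the
extracted per-cell profiles and summaries as CSV.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("fura2track")

DEFAULT_PERIOD_S = 3.0  # acquisition period between ratio pairs, seconds


class Channel(str, Enum):
    """Which excitation wavelength (or derived ratio) a sequence holds."""

    EX340 = "EX340"
    EX380 = "EX380"
    RATIO = "RATIO"


class InputError(ValueError):
    """Invalid user input (missing files, bad parameters)."""


class FormatError(ValueError):
    """Structurally invalid image data (mixed dimensions, wrong dtype)."""


@dataclass
class FrameSequence:
    """A stack of k frames of m x n pixels.

    ``frames`` is stored frame-major: shape (k, m, n).  Raw channels are
    uint8 on the 0-255 scale; the RATIO channel is float64, finite and
    non-negative everywhere.

    Parameters
    ----------
    frames : ndarray, shape (k, m, n)
    channel : Channel
    period : float
        Sampling interval T in seconds between consecutive frames.
    """

    frames: np.ndarray
    channel: Channel = Channel.EX340
    period: float = DEFAULT_PERIOD_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a 3-D (k, m, n) stack, got ndim={self.frames.ndim}"
            )
        if self.n_frames < 1:
            raise FormatError("a sequence needs at least one frame")
        if self.channel is Channel.RATIO:
            if not np.all(np.isfinite(self.frames)):
                raise FormatError("RATIO frames must be finite")
            if np.any(self.frames < 0):
                raise FormatError("RATIO frames must be non-negative")
        if self.period <= 0:
            raise InputError("sampling period must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]


def _rescale_to_uint8(stack: np.ndarray) -> np.ndarray:
    """Map an arbitrary-depth integer stack onto the 0-255 scale."""
    info = np.iinfo(stack.dtype)
    scaled = stack.astype(np.float64) * (255.0 / info.max)
    return np.round(scaled).astype(np.uint8)


def load_tiff_sequence(
    path: str,
    channel: Channel | str = Channel.EX340,
    period: float = DEFAULT_PERIOD_S,
) -> FrameSequence:
    """Load a TIFF sequence into a :class:`FrameSequence`.

    ``path`` may be a directory of single-frame TIFFs (one file per frame,
    lexicographic filename order defines the frame index), a glob pattern,
    or a single multi-page TIFF (page order defines the frame index).

    Raw input deeper than 8 bits is rescaled onto 0-255 with a warning so
    that calibrated thresholds stay comparable across acquisitions.
    """
    channel = Channel(channel)
    if os.path.isdir(path):
        files = sorted(
            f
            for f in (os.path.join(path, n) for n in sorted(os.listdir(path)))
            if f.lower().endswith((".tif", ".tiff"))
        )
    elif any(ch in path for ch in "*?["):
        files = sorted(glob.glob(path))
    else:
        files = [path] if os.path.exists(path) else []
    if not files:
        raise InputError(f"no TIFF files matched {path!r}")

    pages: List[np.ndarray] = []
    for f in files:
        arr = tifffile.imread(f)
        if arr.ndim == 2:
            pages.append(arr)
        elif arr.ndim == 3:  # multi-page file
            pages.extend(arr)
        else:
            raise FormatError(f"{f}: expected single-channel frames, got shape {arr.shape}")

    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame dimensions in {path!r}: {sorted(shapes)}")
    stack = np.stack(pages)
    if stack.dtype != np.uint8:
        if not np.issubdtype(stack.dtype, np.integer):
            raise FormatError(f"raw input must be integer-typed, got {stack.dtype}")
        logger.warning(
            "%s: non-8-bit input (%s); rescaling to 0-255", path, stack.dtype
        )
        stack = _rescale_to_uint8(stack)
    return FrameSequence(stack, channel=channel, period=period)


def make_ratio_sequence(seq340: FrameSequence, seq380: FrameSequence) -> FrameSequence:
    """Build the pixelwise 340/380 ratio sequence.

    Both inputs are left unmodified.  Pixels where the 380-nm denominator is
    zero map to ratio 0 (keeps downstream ROI means finite); their count is
    logged.
    """
    if seq340.channel is not Channel.EX340 or seq380.channel is not Channel.EX380:
        raise InputError("expected an EX340 and an EX380 sequence, in that order")
    if seq340.frames.shape != seq380.frames.shape:
        raise InputError(
            f"dimension mismatch: {seq340.frames.shape} vs {seq380.frames.shape}"
        )
    num = seq340.frames.astype(np.float64)
    den = seq380.frames.astype(np.float64)
    zero = den == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.warning("ratio: %d zero-denominator pixels mapped to 0", n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return FrameSequence(ratio, channel=Channel.RATIO, period=seq340.period)


def save_ratio_tiff(seq: FrameSequence, path: str) -> None:
    """Export a ratio stack as 32-bit float multi-page TIFF for inspection."""
    tifffile.imwrite(path, seq.frames.astype(np.float32), photometric="minisblack")


def write_profiles(
    tracks: Iterable,
    profiles_path: str,
    summary_path: Optional[str] = None,
) -> pd.DataFrame:
    """Write per-(cell, frame) calcium profiles and a per-cell summary.

    The long-format table has one row per (cell, frame) with columns
    ``cell_id, frame, status, x, y, cp_value``; position and CP cells are
    empty on frames where the cell was missing.  The summary table carries
    each cell's mean CP over the frames where it was found, the fraction of
    frames found, and its final status.

    Returns the long-format DataFrame.
    """
    rows = []
    for tr in tracks:
        for rec in tr.history:
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": rec.frame,
                    "status": rec.status,
                    "x": rec.x,
                    "y": rec.y,
                    "cp_value": rec.cp,
                }
            )
    df = pd.DataFrame(
        rows, columns=["cell_id", "frame", "status", "x", "y", "cp_value"]
    )
    try:
        df.to_csv(profiles_path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write profiles to {profiles_path!r}: {exc}") from exc

    if summary_path is None:
        stem, ext = os.path.splitext(profiles_path)
        summary_path = f"{stem}_summary{ext or '.csv'}"
    from .extraction import summarize  # deferred: avoids a module cycle

    summary = summarize(tracks)
    summary.to_csv(summary_path, index=False)
    return df


def read_profiles(profiles_path: str) -> pd.DataFrame:
    """Read back a profiles CSV written by :func:`write_profiles`."""
    return pd.read_csv(profiles_path)
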