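"""Calcium-profile extraction and performance metrics.

The calcium profile (CP) of a cell is the mean ratio intensity inside its
w x w ROI, re-centered on the tracked centroid every frame.  The tracked-
cell density rho_i = 100 * (ONLINE cells) / (binary objects) at frame i is
the run's figure of merit; it can exceed 100% when segmentation merges or
drops blobs while their ROIs stay ONLINE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_ratio import InputError


def extract_cp(ratio_frame: np.ndarray, center: Tuple[float, float], w: int) -> float:
    """Mean ratio intensity over the w x w ROI centered at ``center``.

    ``center`` is (x, y) in pixel coordinates (x = column, y = row).  The
    ROI is cropped at image borders rather than rejected — injured cells
    drift toward the field edge and would otherwise lose their profile.
    """
    frame = np.asarray(ratio_frame, dtype=float)
    m, n = frame.shape
    x, y = center
    if not (0 <= x < n and 0 <= y < m):
        raise InputError(f"ROI center {center} outside image {frame.shape}")
    half_lo = (w - 1) // 2
    half_hi = w // 2
    r0 = max(0, int(round(y)) - half_lo)
    r1 = min(m, int(round(y)) + half_hi + 1)
    c0 = max(0, int(round(x)) - half_lo)
    c1 = min(n, int(round(x)) + half_hi + 1)
    if r0 >= r1 or c0 >= c1:
        raise InputError("ROI entirely outside image")
    return float(frame[r0:r1, c0:c1].mean())


def density_metric(n_online: int, n_blobs: int) -> float:
    """rho = 100 * ONLINE cells / binary objects (percent)."""
    if n_blobs <= 0:
        raise InputError("density metric undefined for a frame with no binary objects")
    return 100.0 * n_online / n_blobs


@dataclass
class PerformanceRecord:
    """Per-frame rho series with its max/min/mean summary (percent)."""

    rho: List[float]
    frames: List[int] = field(default_factory=list)
    rho_max: float = float("nan")
    rho_min: float = float("nan")
    rho_mean: float = float("nan")

    @classmethod
    def from_series(
        cls, rho: Sequence[float], frames: Optional[Sequence[int]] = None
    ) -> "PerformanceRecord":
        rho = list(rho)
        frames = list(frames) if frames is not None else list(range(len(rho)))
        if rho:
            return cls(
                rho=rho,
                frames=frames,
                rho_max=float(max(rho)),
                rho_min=float(min(rho)),
                rho_mean=float(np.mean(rho)),
            )
        return cls(rho=rho, frames=frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frames, "rho": self.rho})


def profile_mse(cp_a: Sequence[float], cp_b: Sequence[float]) -> float:
    """Mean square error between two calcium profiles of equal length."""
    a = np.asarray(cp_a, dtype=float)
    b = np.asarray(cp_b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def summarize(tracks: Iterable) -> pd.DataFrame:
    """Per-cell summary: mean CP over found frames, found fraction, status.

    The mean CP uses only frames where the cell was actually found
    (intersection or Kalman placement); frames it was missing contribute no
    sample.  A cell never found reports NaN.
    """
    rows = []
    for tr in tracks:
        found = [r for r in tr.history if r.found_by != "NONE"]
        n_total = len(tr.history)
        cp_vals = [r.cp for r in found if not math.isnan(r.cp)]
        rows.append(
            {
                "cell_id": tr.cell_id,
                "mean_cp": float(np.mean(cp_vals)) if cp_vals else float("nan"),
                "frames_found": len(found),
                "frames_total": n_total,
                "found_fraction": len(found) / n_total if n_total else float("nan"),
                "final_status": tr.status.value
                if hasattr(tr.status, "value")
                else str(tr.status),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "mean_cp",
            "frames_found",
            "frames_total",
            "found_fraction",
            "final_status",
        ],
    )
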