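"""Multi-cell tracking by mask intersection with Kalman gap-filling.

Each selected cell carries the binary mask of its component in the previous
frame (its *kernel*).  Frame-to-frame association is a logical AND of that
kernel with the current labeled frame: if exactly one component overlaps,
the cell's track label simply updates.  Ambiguous (several overlaps) or
empty intersections fall back on a Kalman prediction of the cell position —
containment in a component first, then nearest centroid within a gate of
w/2 px.

The motion model is constant acceleration per axis with white *jerk* (third
derivative of position) as process noise.  State is
[x, x', x'', y, y', y''] with transition blocks [[1, T, T^2/2], [0, 1, T],
[0, 0, 1]] per axis, observation of (x, y) only, process covariance
Q = q^T q with q = [T^3 sJx/3, T^2 sJx/2, T sJx, T^3 sJy/3, T^2 sJy/2,
T sJy] and observation covariance R = diag(sx^2, sy^2).  Note Q is the full
outer product of the 6-vector q: its x/y cross-terms are kept exactly as
the model defines them.  The (F, H) pair is observable (rank-6
observability matrix), so the filter can reconstruct the full kinematic
state from position observations alone.

Track lifecycle: a per-cell reliability counter counts consecutive missing
frames; any successful find resets it; when it reaches the user-set
reliability limit RL the track flips to OFFLINE, permanently.  Only ONLINE
cells are tracked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io_ratio import FrameSequence, InputError
from .calibration import SegmentationParams
from .segmentation import LabeledFrame
from .extraction import extract_cp, density_metric, PerformanceRecord

logger = logging.getLogger("fura2track")

# Kalman defaults estimated from manually tracked experimental cells
DEFAULT_SIGMA_JX = 0.0269  # px/s^3
DEFAULT_SIGMA_JY = 0.0993  # px/s^3
DEFAULT_SIGMA_OBS = 0.001  # px; tiny so estimates hug the measurements
DEFAULT_RL = 3


class Status(str, Enum):
    ONLINE = "ONLINE"
    OFFLINE = "OFFLINE"


class FoundBy(str, Enum):
    INTERSECTION = "INTERSECTION"
    KALMAN = "KALMAN"
    NONE = "NONE"


@dataclass
class TrackRecord:
    """One frame of one cell's history."""

    frame: int
    status: str
    x: float = float("nan")
    y: float = float("nan")
    cp: float = float("nan")
    found_by: str = FoundBy.NONE.value


@dataclass
class CellTrack:
    """State of one tracked cell.

    ``kernel`` is the binary mask of the cell's component in the last frame
    where it was found; it is what gets intersected with the next frame.
    """

    cell_id: str
    track_label: Optional[int] = None
    status: Status = Status.ONLINE
    reliability_counter: int = 0
    kernel: Optional[np.ndarray] = None
    history: List[TrackRecord] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) for frames where the cell was found."""
        pts = [(r.x, r.y) for r in self.history if r.found_by != FoundBy.NONE.value]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    @property
    def cp_series(self) -> np.ndarray:
        return np.asarray(
            [r.cp for r in self.history if r.found_by != FoundBy.NONE.value], dtype=float
        )


# ---------------------------------------------------------------------------
# Jerk statistics (process-noise estimation from tracked positions)
# ---------------------------------------------------------------------------

@dataclass
class JerkStats:
    """White-jerk standard deviations estimated from c cell tracks."""

    sigma_jx: float
    sigma_jy: float
    n_cells: int
    n_frames: int

    def __post_init__(self) -> None:
        if self.sigma_jx < 0 or self.sigma_jy < 0:
            raise InputError("jerk sigmas must be non-negative")


def estimate_jerk_stats(
    tracks: Sequence[np.ndarray], period: float = 3.0
) -> JerkStats:
    """Estimate the jerk noise from position series.

    Each track is an (n, 2) array of (x, y) with n >= 5.  Per track, the
    jerk series is the third forward difference of position divided by T^3;
    its sample standard deviation (denominator p - 1) is taken per axis,
    and the per-track values are averaged across tracks.
    """
    if not len(tracks):
        raise InputError("need at least one track")
    sx: List[float] = []
    sy: List[float] = []
    n_min = None
    for tr in tracks:
        arr = np.asarray(tr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 5:
            raise InputError("each track must be an (n>=5, 2) position series")
        jerk = np.diff(arr, n=3, axis=0) / period**3
        sx.append(float(np.std(jerk[:, 0], ddof=1)))
        sy.append(float(np.std(jerk[:, 1], ddof=1)))
        n_min = arr.shape[0] if n_min is None else min(n_min, arr.shape[0])
    return JerkStats(
        sigma_jx=float(np.mean(sx)),
        sigma_jy=float(np.mean(sy)),
        n_cells=len(tracks),
        n_frames=int(n_min),
    )


# ---------------------------------------------------------------------------
# Kalman estimator
# ---------------------------------------------------------------------------

class KalmanModel:
    """Six-state constant-acceleration Kalman filter for one cell.

    State ordering is [x, x', x'', y, y', y''] (px, px/s, px/s^2).
    Initialization: position from the first observed centroid, zero
    velocity and acceleration, P0 = diag(sx^2, 1, 1, sy^2, 1, 1) — a
    zero-motion prior suited to slowly moving cells.
    """

    def __init__(
        self,
        stats: Optional[JerkStats] = None,
        sigma_obs: Tuple[float, float] = (DEFAULT_SIGMA_OBS, DEFAULT_SIGMA_OBS),
        period: float = 3.0,
        initial_position: Tuple[float, float] = (0.0, 0.0),
    ) -> None:
        if period <= 0:
            raise InputError("sampling period must be positive")
        sjx = stats.sigma_jx if stats is not None else DEFAULT_SIGMA_JX
        sjy = stats.sigma_jy if stats is not None else DEFAULT_SIGMA_JY
        sx, sy = sigma_obs
        if sx <= 0 or sy <= 0 or sjx < 0 or sjy < 0:
            raise InputError("noise sigmas must be positive (obs) / non-negative (jerk)")
        T = float(period)
        self.T = T
        axis = np.array([[1.0, T, T * T / 2.0], [0.0, 1.0, T], [0.0, 0.0, 1.0]])
        self.F = np.zeros((6, 6))
        self.F[:3, :3] = axis
        self.F[3:, 3:] = axis
        self.H = np.zeros((2, 6))
        self.H[0, 0] = 1.0
        self.H[1, 3] = 1.0
        q = np.array(
            [
                T**3 * sjx / 3.0,
                T**2 * sjx / 2.0,
                T * sjx,
                T**3 * sjy / 3.0,
                T**2 * sjy / 2.0,
                T * sjy,
            ]
        )
        self.q = q
        self.Q = np.outer(q, q)
        self.R = np.diag([sx**2, sy**2])
        x0, y0 = initial_position
        self.state = np.array([x0, 0.0, 0.0, y0, 0.0, 0.0])
        self.P = np.diag([sx**2, 1.0, 1.0, sy**2, 1.0, 1.0])

    @property
    def position(self) -> Tuple[float, float]:
        pos = self.H @ self.state
        return float(pos[0]), float(pos[1])

    def predict(self) -> Tuple[float, float]:
        """Time update: advance state one period; returns predicted (x, y)."""
        self.state = self.F @ self.state
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.position

    def correct(self, observation: Tuple[float, float]) -> Tuple[float, float]:
        """Measurement update with the observed centroid; returns (x, y)."""
        z = np.asarray(observation, dtype=float)
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.state = self.state + K @ (z - self.H @ self.state)
        ikh = np.eye(6) - K @ self.H
        # Joseph form keeps P symmetric PSD under round-off
        self.P = ikh @ self.P @ ikh.T + K @ self.R @ K.T
        return self.position


def build_kalman(
    stats: Optional[JerkStats] = None,
    sigma_obs: Tuple[float, float] = (DEFAULT_SIGMA_OBS, DEFAULT_SIGMA_OBS),
    period: float = 3.0,
    initial_position: Tuple[float, float] = (0.0, 0.0),
) -> KalmanModel:
    """Assemble a :class:`KalmanModel` (defaults: experiment-derived sigmas)."""
    return KalmanModel(stats, sigma_obs, period, initial_position)


def kalman_predict(model: KalmanModel) -> Tuple[float, float]:
    return model.predict()


def kalman_correct(model: KalmanModel, observation: Tuple[float, float]) -> KalmanModel:
    model.correct(observation)
    return model


def observability_rank(model: KalmanModel) -> int:
    """Rank of the observability matrix [H; HF; ...; HF^5]."""
    blocks = []
    Fp = np.eye(6)
    for _ in range(6):
        blocks.append(model.H @ Fp)
        Fp = Fp @ model.F
    return int(np.linalg.matrix_rank(np.vstack(blocks)))


def run_kalman_filter(
    observations: np.ndarray,
    missing: Optional[Set[int]] = None,
    stats: Optional[JerkStats] = None,
    sigma_obs: Tuple[float, float] = (DEFAULT_SIGMA_OBS, DEFAULT_SIGMA_OBS),
    period: float = 3.0,
) -> np.ndarray:
    """Filter a single (n, 2) observation series; returns (n, 2) estimates.

    Frames listed in ``missing`` get a time update only (prediction with no
    correction) — the regime a cell is in while it has transiently vanished.
    The frame-0 estimate is the initialization at the first observation.
    """
    obs = np.asarray(observations, dtype=float)
    missing = missing or set()
    model = build_kalman(stats, sigma_obs, period, initial_position=tuple(obs[0]))
    est = np.zeros_like(obs)
    est[0] = model.position
    for k in range(1, len(obs)):
        model.predict()
        if k not in missing:
            model.correct(tuple(obs[k]))
        est[k] = model.position
    return est


# ---------------------------------------------------------------------------
# Intersection association
# ---------------------------------------------------------------------------

def intersect_kernel(prev_cell_mask: np.ndarray, current: LabeledFrame) -> Set[int]:
    """Labels of current-frame components overlapping the cell's kernel."""
    kernel = np.asarray(prev_cell_mask, dtype=bool)
    if kernel.shape != current.labels.shape:
        raise InputError("kernel and frame dimensions differ")
    return set(int(v) for v in np.unique(current.labels[kernel]) if v != 0)


MISSING = None  # sentinel: no label resolved for this frame


def resolve_label(
    candidates: Set[int],
    model: KalmanModel,
    current: LabeledFrame,
    gate: float,
) -> Optional[int]:
    """Resolve the cell's current-frame label from intersection candidates.

    Exactly one candidate wins outright.  Otherwise the Kalman-predicted
    position decides: a component containing the prediction (restricted to
    the candidates when there are any), else the component whose centroid
    is nearest the prediction within ``gate`` px.  Returns ``None`` when
    the cell cannot be placed (MISSING).
    """
    if len(candidates) == 1:
        return next(iter(candidates))
    if current.n_components == 0:
        return MISSING
    px, py = model.position
    pool = sorted(candidates) if candidates else list(range(1, current.n_components + 1))

    row, col = int(round(py)), int(round(px))
    if 0 <= row < current.labels.shape[0] and 0 <= col < current.labels.shape[1]:
        lab = int(current.labels[row, col])
        if lab != 0 and lab in pool:
            return lab

    cents = current.centroids[np.asarray(pool) - 1]
    d2 = (cents[:, 0] - px) ** 2 + (cents[:, 1] - py) ** 2
    best = int(np.argmin(d2))
    if d2[best] <= gate * gate:
        return pool[best]
    return MISSING


# ---------------------------------------------------------------------------
# Lifecycle stepping
# ---------------------------------------------------------------------------

@dataclass
class TrackingConfig:
    """Run-level tracking knobs."""

    rl: int = DEFAULT_RL
    sigma_jx: float = DEFAULT_SIGMA_JX
    sigma_jy: float = DEFAULT_SIGMA_JY
    sigma_obs: Tuple[float, float] = (DEFAULT_SIGMA_OBS, DEFAULT_SIGMA_OBS)

    def jerk_stats(self) -> JerkStats:
        return JerkStats(self.sigma_jx, self.sigma_jy, n_cells=0, n_frames=0)


def step_tracking(
    current: LabeledFrame,
    ratio_frame: np.ndarray,
    tracks: Sequence[CellTrack],
    models: Dict[str, KalmanModel],
    frame_index: int,
    params: SegmentationParams,
    rl: int = DEFAULT_RL,
) -> None:
    """Advance every ONLINE track from its kernel into ``current``.

    Found cells store centroid + CP, reset the reliability counter, and get
    a full predict + correct.  Missing cells get a predict-only coast and a
    counter increment; at counter == RL the track flips OFFLINE for good.
    """
    for tr in tracks:
        if tr.status is Status.OFFLINE:
            tr.history.append(TrackRecord(frame=frame_index, status=Status.OFFLINE.value))
            continue
        model = models[tr.cell_id]
        model.predict()
        candidates = intersect_kernel(tr.kernel, current)
        label = resolve_label(candidates, model, current, gate=params.w / 2.0)
        if label is not MISSING:
            x, y = current.centroid(label)
            model.correct((x, y))
            cp = extract_cp(ratio_frame, (x, y), params.w)
            found_by = (
                FoundBy.INTERSECTION if len(candidates) == 1 else FoundBy.KALMAN
            )
            tr.track_label = label
            tr.kernel = current.component_mask(label)
            tr.reliability_counter = 0
            tr.history.append(
                TrackRecord(
                    frame=frame_index,
                    status=Status.ONLINE.value,
                    x=x,
                    y=y,
                    cp=cp,
                    found_by=found_by.value,
                )
            )
        else:
            tr.track_label = None
            tr.reliability_counter += 1
            if tr.reliability_counter >= rl:
                tr.status = Status.OFFLINE
                logger.info(
                    "cell %s OFFLINE at frame %d (counter reached RL=%d)",
                    tr.cell_id,
                    frame_index,
                    rl,
                )
            tr.history.append(
                TrackRecord(frame=frame_index, status=tr.status.value)
            )


@dataclass
class TrackingResult:
    tracks: List[CellTrack]
    performance: PerformanceRecord


def _init_tracks(
    first: LabeledFrame,
    ratio_frame: np.ndarray,
    selections,
    params: SegmentationParams,
    config: TrackingConfig,
    period: float,
) -> Tuple[List[CellTrack], Dict[str, KalmanModel]]:
    if isinstance(selections, str) and selections.lower() == "all":
        labels = list(range(1, first.n_components + 1))
    else:
        # selections: iterable of (x, y) seed points mapped to the nearest component
        labels = []
        for x, y in selections:
            row, col = int(round(y)), int(round(x))
            lab = 0
            if 0 <= row < first.labels.shape[0] and 0 <= col < first.labels.shape[1]:
                lab = int(first.labels[row, col])
            if lab == 0 and first.n_components:
                d2 = (first.centroids[:, 0] - x) ** 2 + (first.centroids[:, 1] - y) ** 2
                lab = int(np.argmin(d2)) + 1
            if lab:
                labels.append(lab)
    tracks: List[CellTrack] = []
    models: Dict[str, KalmanModel] = {}
    stats = config.jerk_stats()
    for i, lab in enumerate(labels, start=1):
        x, y = first.centroid(lab)
        cid = f"A{i:03d}"
        tr = CellTrack(
            cell_id=cid,
            track_label=lab,
            kernel=first.component_mask(lab),
        )
        tr.history.append(
            TrackRecord(
                frame=0,
                status=Status.ONLINE.value,
                x=x,
                y=y,
                cp=extract_cp(ratio_frame, (x, y), params.w),
                found_by=FoundBy.INTERSECTION.value,
            )
        )
        tracks.append(tr)
        models[cid] = build_kalman(
            stats, config.sigma_obs, period, initial_position=(x, y)
        )
    return tracks, models


def run_tracking(
    labeled_seq: Sequence[LabeledFrame],
    ratio_seq: FrameSequence,
    selections="all",
    params: Optional[SegmentationParams] = None,
    config: Optional[TrackingConfig] = None,
) -> TrackingResult:
    """Track selected cells across a segmented sequence.

    ``selections`` is either ``"all"`` (one track per component of the
    first frame) or an iterable of (x, y) seed points.  Returns the tracks
    and the per-frame tracked-cell density rho (percent; frames with zero
    binary objects are skipped from the summaries with a warning).
    """
    if len(labeled_seq) < 2:
        raise InputError("tracking needs at least two frames")
    if len(labeled_seq) != ratio_seq.n_frames:
        raise InputError("labeled sequence and ratio sequence lengths differ")
    params = params or SegmentationParams(w=20)
    config = config or TrackingConfig()

    tracks, models = _init_tracks(
        labeled_seq[0], ratio_seq.frames[0], selections, params, config, ratio_seq.period
    )
    if not tracks:
        logger.warning("no cells selected on the first frame; empty result")

    frames_idx: List[int] = []
    rho: List[float] = []

    def record_rho(i: int) -> None:
        n_online = sum(t.status is Status.ONLINE for t in tracks)
        n_blobs = labeled_seq[i].n_components
        if n_blobs == 0:
            logger.warning("frame %d has no binary objects; rho undefined, skipped", i)
            return
        frames_idx.append(i)
        rho.append(density_metric(n_online, n_blobs))

    record_rho(0)
    for i in range(1, len(labeled_seq)):
        step_tracking(
            labeled_seq[i],
            ratio_seq.frames[i],
            tracks,
            models,
            frame_index=i,
            params=params,
            rl=config.rl,
        )
        record_rho(i)

    perf = PerformanceRecord.from_series(rho, frames=frames_idx)
    return TrackingResult(tracks=tracks, performance=perf)
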