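"""Synthetic dual-wavelength phantoms and the sinusoidal estimator test.

Two generators with exact ground truth drive every downstream check:

* :func:`gen_sinusoid_test` renders a single bright blob whose centroid
  follows x = c, y = A cos(2 pi f t) — the deterministic trajectory used to
  exercise the Kalman estimator (f counts full cycles over the sequence; a
  literal 4 Hz at a 3-s sampling period would alias beyond recognition).
* :func:`gen_phantom` renders a monolayer of non-overlapping elliptical
  cells on a noisy background, with slow random motion, optional jump
  events, per-cell dropout frames and a biphasic calcium waveform.  The
  340-nm channel is modulated by the waveform and the 380-nm channel is
  left constant, so the pixelwise ratio reproduces the target waveform
  everywhere — the generated calcium profile is known analytically.

Cells are rendered as anti-aliased filled disks (one-pixel linear edge
falloff); channel noise is additive Gaussian before 8-bit quantization.
The same seed yields bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io_ratio import FrameSequence, Channel, InputError

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "gen_sinusoid_test",
    "measure_centroids",
    "gen_phantom",
    "gen_jerk_tracks",
    "biphasic_waveform",
    "random_dropout_schedule",
    "kalman_sinusoid_benchmark",
    "DEFAULT_GAP_FRAMES",
    "trajectory_mse",
]


def _render_disk(
    canvas: np.ndarray, cx: float, cy: float, radius: float, amplitude: float
) -> None:
    """Add an anti-aliased disk: coverage ramps linearly over the last px."""
    m, n = canvas.shape
    r_int = int(np.ceil(radius)) + 1
    row0 = max(0, int(np.floor(cy)) - r_int)
    row1 = min(m, int(np.ceil(cy)) + r_int + 1)
    col0 = max(0, int(np.floor(cx)) - r_int)
    col1 = min(n, int(np.ceil(cx)) + r_int + 1)
    if row0 >= row1 or col0 >= col1:
        return
    yy, xx = np.mgrid[row0:row1, col0:col1]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    coverage = np.clip(radius + 0.5 - d, 0.0, 1.0)
    canvas[row0:row1, col0:col1] += amplitude * coverage


def _quantize(canvas: np.ndarray) -> np.ndarray:
    return np.round(np.clip(canvas, 0, 255)).astype(np.uint8)


# ---------------------------------------------------------------------------
# Sinusoid estimator test
# ---------------------------------------------------------------------------

def gen_sinusoid_test(
    bias_c: float = 48.0,
    peak_to_peak: float = 36.0,
    f: float = 4.0,
    n_frames: int = 100,
    object_area: float = 100.0,
    dropout_frames: Sequence[int] = (),
    seed: Optional[int] = None,
    shape: Tuple[int, int] = (128, 96),
    background: float = 20.0,
    cell_level: float = 180.0,
    noise_sd: float = 0.0,
    period: float = 3.0,
) -> Tuple[FrameSequence, np.ndarray]:
    """Render the deterministic single-cell sinusoid sequence.

    The blob of ``object_area`` px^2 sits at x = bias_c,
    y = y_mid + A cos(2 pi f t) with A = peak_to_peak / 2 and t = i/n taking
    ``f`` full cycles over the ``n_frames``-frame sequence.  Frames listed
    in ``dropout_frames`` are rendered without the blob.  Returns the
    sequence and the exact (n, 2) trajectory.
    """
    if n_frames < 10:
        raise InputError("sinusoid test needs at least 10 frames")
    m, n = shape
    amp = peak_to_peak / 2.0
    if peak_to_peak >= m:
        raise InputError("peak-to-peak amplitude must be smaller than the image height")
    radius = np.sqrt(object_area / np.pi)
    y_mid = m / 2.0
    t = np.arange(n_frames) / n_frames
    truth = np.column_stack(
        [np.full(n_frames, float(bias_c)), y_mid + amp * np.cos(2 * np.pi * f * t)]
    )
    margin = radius + 1
    if (
        truth[:, 0].min() < margin
        or truth[:, 0].max() > n - 1 - margin
        or truth[:, 1].min() < margin
        or truth[:, 1].max() > m - 1 - margin
    ):
        raise InputError("trajectory leaves the frame; enlarge the image or shrink A")

    rng = np.random.default_rng(seed)
    dropped = set(int(i) for i in dropout_frames)
    frames = np.zeros((n_frames, m, n), dtype=np.uint8)
    for i in range(n_frames):
        canvas = np.full((m, n), background, dtype=float)
        if i not in dropped:
            _render_disk(canvas, truth[i, 0], truth[i, 1], radius, cell_level - background)
        if noise_sd > 0:
            canvas += rng.normal(0.0, noise_sd, size=canvas.shape)
        frames[i] = _quantize(canvas)
    return FrameSequence(frames, channel=Channel.EX340, period=period), truth


def measure_centroids(seq: FrameSequence, threshold: Optional[float] = None) -> np.ndarray:
    """Blob centroid per frame by half-maximum thresholding.

    Returns an (n, 2) array of (x, y); frames with no above-threshold pixel
    (dropouts) give NaN rows.
    """
    frames = seq.frames.astype(float)
    if threshold is None:
        threshold = (frames.min() + frames.max()) / 2.0
    out = np.full((seq.n_frames, 2), np.nan)
    for i in range(seq.n_frames):
        rows, cols = np.nonzero(frames[i] > threshold)
        if rows.size:
            out[i] = [cols.mean(), rows.mean()]
    return out


# ---------------------------------------------------------------------------
# Multi-cell phantom
# ---------------------------------------------------------------------------

def biphasic_waveform(
    n_frames: int,
    baseline: float = 0.9,
    peak_amplitude: float = 0.9,
    peak_frame: int = 30,
    plateau: float = 1.2,
    rise_frames: int = 3,
    decay_tau: float = 15.0,
) -> np.ndarray:
    """Agonist-like calcium waveform on the ratio scale.

    Baseline, linear rise over ``rise_frames`` to baseline + peak_amplitude
    at ``peak_frame``, then exponential decay toward the ``plateau`` level —
    the rapid transient followed by a sustained plateau typical of
    stimulated endothelium.
    """
    t = np.arange(n_frames, dtype=float)
    w = np.full(n_frames, baseline)
    peak = baseline + peak_amplitude
    onset = peak_frame - rise_frames
    rising = (t >= onset) & (t <= peak_frame)
    w[rising] = baseline + peak_amplitude * (t[rising] - onset) / max(rise_frames, 1)
    after = t > peak_frame
    w[after] = plateau + (peak - plateau) * np.exp(-(t[after] - peak_frame) / decay_tau)
    return w


@dataclass
class PhantomSpec:
    """Full description of a multi-cell phantom.

    ``dropout`` maps cell index -> set of frame indices where that cell is
    not rendered.  ``jump`` optionally displaces every cell by (dx, dy)
    starting at the given frame (injury-like motion).  The waveform
    parameters shape the shared calcium profile on the ratio scale.
    """

    shape: Tuple[int, int] = (256, 256)
    n_frames: int = 50
    n_cells: int = 30
    area_mean: float = 100.0
    area_sd: float = 10.0
    cell_level: float = 135.0  # 380-nm cell intensity; 340 nm is this times W(t)
    background: float = 60.0  # 380-nm background; 340 nm is this times W(t)
    motion_sd: float = 0.5  # per-axis random-walk step, px/frame
    min_separation: float = 20.0  # min center distance: single-nucleus ROIs must not overlap
    jump: Optional[Tuple[int, Tuple[float, float]]] = None
    dropout: Dict[int, Set[int]] = field(default_factory=dict)
    baseline: float = 0.9
    peak_amplitude: float = 0.9
    peak_frame: int = 30
    plateau: float = 1.2
    noise_sd: float = 5.0
    period: float = 3.0
    seed: Optional[int] = 0


@dataclass
class PhantomResult:
    seq340: FrameSequence
    seq380: FrameSequence
    positions: np.ndarray  # (k, n_cells, 2) exact (x, y) every frame
    visible: np.ndarray  # (k, n_cells) bool, False on dropout frames
    cp_truth: np.ndarray  # (k,) waveform shared by all cells (ratio scale)
    radii: np.ndarray  # (n_cells,)


def _place_cells(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n_cells: int,
    radii: np.ndarray,
    margin: float,
    min_separation: float,
) -> np.ndarray:
    """Rejection-sample initial centers at least ``min_separation`` apart."""
    m, n = shape
    centers: List[Tuple[float, float]] = []
    sep2 = max(min_separation, 2.0 * float(radii.max()) + 2.0) ** 2
    for i in range(n_cells):
        for _ in range(3000):
            x = rng.uniform(margin + radii[i], n - 1 - margin - radii[i])
            y = rng.uniform(margin + radii[i], m - 1 - margin - radii[i])
            ok = all((x - cx) ** 2 + (y - cy) ** 2 > sep2 for cx, cy in centers)
            if ok:
                centers.append((x, y))
                break
        else:
            raise InputError(
                f"cannot pack {n_cells} non-overlapping cells into image {shape}"
            )
    return np.asarray(centers)


def gen_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render the dual-wavelength phantom described by ``spec``.

    The 380-nm channel holds constant intensities; the 340-nm channel is
    the same scene multiplied by the calcium waveform W(t), so the
    pixelwise ratio equals W(t) everywhere (cells and background alike) and
    every cell's true CP is the waveform itself, independent of ROI
    placement.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.shape
    k = spec.n_frames
    radii = np.sqrt(
        np.clip(rng.normal(spec.area_mean, spec.area_sd, spec.n_cells), 20.0, None)
        / np.pi
    )
    margin = 10.0
    start = _place_cells(rng, spec.shape, spec.n_cells, radii, margin, spec.min_separation)

    steps = rng.normal(0.0, spec.motion_sd, size=(k, spec.n_cells, 2))
    steps[0] = 0.0
    positions = start[None, :, :] + np.cumsum(steps, axis=0)
    if spec.jump is not None:
        jump_frame, (dx, dy) = spec.jump
        positions[jump_frame:] += np.asarray([dx, dy])
    # keep every center renderable
    positions[..., 0] = np.clip(positions[..., 0], radii + 2, n - 3 - radii)
    positions[..., 1] = np.clip(positions[..., 1], radii[None, :] + 2, m - 3 - radii[None, :])

    cp = biphasic_waveform(
        k, spec.baseline, spec.peak_amplitude, spec.peak_frame, spec.plateau
    )
    visible = np.ones((k, spec.n_cells), dtype=bool)
    for cell, frames_off in spec.dropout.items():
        for fr in frames_off:
            visible[int(fr), int(cell)] = False

    f340 = np.zeros((k, m, n), dtype=np.uint8)
    f380 = np.zeros((k, m, n), dtype=np.uint8)
    for i in range(k):
        scene = np.full((m, n), spec.background, dtype=float)
        for c in range(spec.n_cells):
            if visible[i, c]:
                _render_disk(
                    scene,
                    positions[i, c, 0],
                    positions[i, c, 1],
                    radii[c],
                    spec.cell_level - spec.background,
                )
        noise340 = rng.normal(0.0, spec.noise_sd, size=scene.shape) if spec.noise_sd else 0.0
        noise380 = rng.normal(0.0, spec.noise_sd, size=scene.shape) if spec.noise_sd else 0.0
        f340[i] = _quantize(scene * cp[i] + noise340)
        f380[i] = _quantize(scene + noise380)

    return PhantomResult(
        seq340=FrameSequence(f340, channel=Channel.EX340, period=spec.period),
        seq380=FrameSequence(f380, channel=Channel.EX380, period=spec.period),
        positions=positions,
        visible=visible,
        cp_truth=cp,
        radii=radii,
    )


def random_dropout_schedule(
    n_cells: int,
    n_frames: int,
    fraction: float,
    block_len: int = 2,
    seed: Optional[int] = None,
    first_frame: int = 2,
) -> Dict[int, Set[int]]:
    """Transient dropout blocks covering ~``fraction`` of each cell's frames.

    Blocks of ``block_len`` consecutive frames are placed uniformly (no
    overlap) from ``first_frame`` on, emulating cells that momentarily
    vanish under smooth-muscle contraction.
    """
    rng = np.random.default_rng(seed)
    out: Dict[int, Set[int]] = {}
    n_blocks = max(0, int(round(fraction * n_frames / block_len)))
    for c in range(n_cells):
        frames: Set[int] = set()
        tries = 0
        while len(frames) < n_blocks * block_len and tries < 200:
            tries += 1
            s = int(rng.integers(first_frame, n_frames - block_len))
            block = set(range(s, s + block_len))
            # keep blocks separated so gaps stay shorter than typical RLs
            if all(abs(f - g) > block_len for f in block for g in frames):
                frames |= block
        out[c] = frames
    return out


def gen_jerk_tracks(
    n_tracks: int = 15,
    n_frames: int = 100,
    sigma_jx: float = 0.0269,
    sigma_jy: float = 0.0993,
    period: float = 3.0,
    seed: Optional[int] = None,
    start: Tuple[float, float] = (100.0, 100.0),
) -> List[np.ndarray]:
    """Position series whose third difference is white jerk of known sigma.

    Built so that diff(pos, 3)/T^3 is exactly the drawn white-noise jerk —
    the generating model the jerk-statistics estimator assumes.
    """
    rng = np.random.default_rng(seed)
    tracks: List[np.ndarray] = []
    for _ in range(n_tracks):
        cols = []
        for sigma in (sigma_jx, sigma_jy):
            jerk = rng.normal(0.0, sigma, size=n_frames - 3)
            d3 = jerk * period**3
            d2 = np.concatenate([[0.0], np.cumsum(d3)])
            d1 = np.concatenate([[0.0], np.cumsum(d2)])
            pos = np.concatenate([[0.0], np.cumsum(d1)])
            cols.append(pos)
        tracks.append(np.column_stack(cols) + np.asarray(start))
    return tracks


def kalman_sinusoid_benchmark(
    gap_frames: Optional[Sequence[int]] = None,
    n_frames: int = 100,
    peak_to_peak: float = 36.0,
    f: float = 4.0,
    object_area: float = 100.0,
    seed: Optional[int] = None,
    period: float = 3.0,
) -> Tuple[float, float]:
    """Per-axis trajectory MSE of the Kalman estimate on the sinusoid test.

    Renders the deterministic sequence, measures blob centroids, runs the
    filter with the experiment-derived noise parameters (prediction only on
    ``gap_frames``, where the blob is not rendered), and returns the mean
    squared (x, y) error of the estimate against the analytic trajectory.
    """
    from .tracking import run_kalman_filter  # deferred: tracking builds on synthetic tests

    gap = set(int(i) for i in gap_frames) if gap_frames else set()
    seq, truth = gen_sinusoid_test(
        peak_to_peak=peak_to_peak,
        f=f,
        n_frames=n_frames,
        object_area=object_area,
        dropout_frames=sorted(gap),
        seed=seed,
        period=period,
    )
    obs = measure_centroids(seq)
    est = run_kalman_filter(obs, missing=gap, period=period)
    return trajectory_mse(est, truth)


# default 5-frame mid-sequence gap for the prediction-only benchmark
DEFAULT_GAP_FRAMES = tuple(range(47, 52))


def trajectory_mse(estimated: np.ndarray, truth: np.ndarray) -> Tuple[float, float]:
    """Per-axis mean squared error between two (n, 2) trajectories."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise InputError(f"trajectory length mismatch: {est.shape} vs {tru.shape}")
    err = est - tru
    return float(np.mean(err[:, 0] ** 2)), float(np.mean(err[:, 1] ** 2))
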