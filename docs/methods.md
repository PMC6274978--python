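# Methods

## Problem and data model

Fura-2 ratiometric imaging of an endothelial monolayer yields two 8-bit
single-channel TIFF sequences, one per excitation wavelength (340 and
380 nm), sampled every T = 3 s for a few hundred frames at 640×480 or
768×576 px. The pixelwise quotient of the 340-nm frame over the 380-nm
frame ("ratio image") increases with intracellular Ca²⁺; a cell's calcium
profile (CP) is the time series of mean ratio intensity inside a square
region of interest (ROI) centered on its nucleus. Cell nuclei appear as
bright blobs on a dimmer background in the 340-nm channel, which therefore
drives calibration, segmentation and tracking; the 380-nm channel is used
only to form the ratio. Zero-valued 380-nm pixels map to ratio 0 rather
than infinity so that downstream ROI means remain finite; occurrences are
logged. Raw inputs deeper than 8 bits are rescaled onto the 0–255 integer
scale so the calibrated thresholds are comparable across acquisitions.

## Calibration

The single scale of the whole pipeline is the window side
w = [a·√µ_areas], where µ_areas is the mean pixel area of a handful of
user-selected cell ROIs and the bracket is round-half-up. It sets the
median-filter window (w/8, rounded, floored at 1), the Niblack
neighborhood, the CP ROI side and the tracking gate (w/2). The scale
factor defaults to a = 2; `calibrate_a` reproduces its selection by grid
search, running the full segmentation at each candidate a and scoring the
mean mask MSE against reference masks (masks treated as 0/1 reals, so the
MSE is the fraction of disagreeing pixels). Ties break toward smaller a.

## Segmentation

Per frame: median filter → linear histogram stretch to [0, 255] →
Niblack local thresholding → morphological conditioning → labeling.

Numerical choices that the method's description leaves open, fixed here:

* **Integer pixel scale.** The stretched frame is re-quantized to uint8
  (round-half-up). Integer pixel values make the integral-image window
  sums exact in float64, so a perfectly uniform region yields s = 0 and
  T = m exactly and the strict foreground test I > T classifies it as all
  background with no dependence on summation order. A constant frame
  passes the stretch unchanged (avoids 0/0).
* **Border policy.** Local mean and standard deviation are computed over
  the intersection of the w×w window with the image (windows cropped, not
  padded), which avoids padding artifacts inflating s near edges. The
  integral-image implementation is exactly equivalent to the direct
  per-pixel computation; tests assert bit-identical masks.
* **Std formula.** Population std s = √(E[I²] − E[I]²), negative round-off
  clamped at 0.
* **Conditioning.** Opening with a disk of radius 3, hole filling
  (background not 4-connected to the border becomes foreground), dilation
  with a disk of radius 1 — in that order.
* **Labeling.** 8-connected components, labels in raster order of first
  pixel; centroids are unweighted pixel means, x = column, y = row,
  0-based, origin top-left.

## Tracking

Only ONLINE cells are tracked. Each cell carries the binary mask of its
component in the last frame where it was found (its kernel). Association
into the next frame is the logical AND of kernel and labeled frame:

* exactly one overlapping component → that component;
* zero or several → the Kalman-predicted position decides: first
  containment in a component (restricted to the overlap candidates when
  any exist), then the nearest component centroid within a gate of w/2 px;
* otherwise the cell is missing this frame.

A found cell stores its centroid and CP, resets its reliability counter
and receives a full predict + correct. A missing cell gets one predict per
missing frame (the state coasts, so a reappearing cell is gated against an
up-to-date prediction) and its counter increments; when the counter
reaches the reliability limit RL (default 3, configurable) the track turns
OFFLINE and is never revived. Any successful find — by intersection or by
Kalman placement — resets the counter. Two tracks may resolve to the same
component; no exclusivity is imposed (ROI/blob mismatch is an observed
regime, reflected in the density metric exceeding 100%).

### Motion model

Constant acceleration per axis with white jerk (third position derivative)
as process noise. State [x, ẋ, ẍ, y, ẏ, ÿ]; per-axis transition blocks
[[1, T, T²/2], [0, 1, T], [0, 0, 1]]; observation of position only. The
process covariance is Q = qᵀq with
q = [T³σ_Jx/3, T²σ_Jx/2, Tσ_Jx, T³σ_Jy/3, T²σ_Jy/2, Tσ_Jy] — the full
outer product of the 6-vector q, kept exactly as the model defines it,
x/y cross-terms included. Those cross-terms couple the axes: on the
sinusoid benchmark they are why the constant-x axis accumulates more error
than the oscillating y axis. The pair (F, H) is observable (the stacked
observability matrix [H; HF; …; HF⁵] has rank 6), so the full kinematic
state is reconstructible from position measurements.

Defaults (estimable from data with `estimate_jerk_stats`): σ_Jx = 0.0269,
σ_Jy = 0.0993 px/s³ — obtained by manually tracking c = 15 cells over
p = 100 frames, taking the third forward difference of position over T³,
the per-track sample std (denominator p − 1), and the mean across tracks.
Observation noise σ_x = σ_y = 0.001 px, deliberately tiny so corrected
estimates hug the measured centroids while Q still regularizes the update.
Initialization (unspecified in the method's description): state at the
first observed centroid with zero velocity and acceleration, and
P₀ = diag(σ_x², 1, 1, σ_y², 1, 1) — a zero-motion prior suited to slowly
moving cells with moderately uninformative derivative variances (1 px/s,
1 px/s² one-sigma). Correction uses the Joseph form to keep P symmetric
positive semi-definite under round-off.

## Extraction

The CP is the mean ratio over the w×w ROI centered (rounded to the pixel
grid) on the current centroid, cropped at image borders rather than
rejected, since injured cells drift toward the field edge. CPs are sampled
only on frames where the cell was found; missing frames contribute no
sample rather than a zero (a zero would fabricate a false negative in the
Ca²⁺ signal). The per-frame figure of merit is
ρᵢ = 100 · (ONLINE cells)/(binary objects); frames with no binary objects
are excluded from the summaries with a warning. ρ may exceed 100% when
blobs vanish or merge while their tracks remain ONLINE. Because a larger
RL can only lengthen each cell's ONLINE span (tracks are independent and
OFFLINE is absorbing), mean ρ is nondecreasing in RL on any fixed input.

## Synthetic data

The generators define the conditions every quantitative claim is tested
under.

**Sinusoid estimator benchmark.** One anti-aliased disk of the average
cell area (100 px², radius ≈ 5.6 px) rendered at x = c,
y = A·cos(2πft), A = 18 px (36 px peak-to-peak), over 100 frames.
The frequency f = 4 is interpreted as four full cycles over the sequence
(t normalized to [0, 1)): at T = 3 s a literal 4 Hz would alias beyond
recognition. Observations are centroids measured from the rendered frames
by half-maximum thresholding; the benchmark reports per-axis MSE of the
filtered trajectory against the analytic one. The prediction-only variant
removes a contiguous 5-frame block mid-sequence (frames 47–51) — the count
is a choice, configurable, standing in for "several missed points". Both
variants keep the per-axis MSE well inside the average ROI area
((w/2)² = 100 px²), the operational requirement for re-finding a lost
cell. Because the filter initialization, t-vector semantics and gap
pattern behind the published benchmark table are not recorded, its
absolute MSE values are reproduction targets at order-of-magnitude
fidelity only; the implementation matches them at that fidelity and
reproduces their qualitative signature (MSE_x ≫ MSE_y via the Q
cross-terms; the gap run strictly worse on the gapped axis).

**Multi-cell phantom.** Non-overlapping anti-aliased disks (area
100 ± 10 px²) on a noisy background, with per-axis Gaussian random-walk
motion (default 0.5 px/frame), optional global jump events (injury-like),
per-cell dropout frames (transient vanishing), and a biphasic calcium
waveform (baseline 0.9, peak 1.8 at frame 30 after a 3-frame rise,
exponential decay toward a 1.2 plateau — the agonist-evoked transient plus
plateau typical of stimulated endothelium). The 380-nm channel holds a
static scene (cells 135, background 60, 8-bit); the 340-nm channel is the
same scene multiplied by the waveform, so the pixelwise ratio equals the
waveform everywhere and each cell's true CP is known analytically,
independent of ROI placement. Channel noise is additive Gaussian
(sd 5/255) before quantization. Initial centers are at least 20 px apart
(the calibrated ROI side for the default areas): the method assumes one
nucleus per w×w square, so initial ROIs must not overlap. Same seed,
bit-identical stacks.

What the phantom does **not** emulate: the correlated background motion of
the smooth-muscle layer (each cell moves independently here), optics PSF
and vignetting, photobleaching, and intensity loss preceding cell death.
Passing tests therefore demonstrate the correctness of the algorithmic
chain under the stated motion/noise/dropout regime, not performance on
real aorta sequences, whose absolute benchmark figures depend on
unreleased recordings.

**Jerk-recovery tracks.** Position series constructed so their third
difference over T³ is exactly the drawn white-noise jerk — the generating
model the estimator assumes; used to verify parameter recovery (relative
error < 15% at c = 15, p = 100 across 100 replicates, against a sampling
standard error of ≈ 2%).

## Problem sizes used by the test suite

Phantom checks run at 50 frames × 30 cells (256×256 px) for the
end-to-end accuracy test, 40 × 12 for the RL sweep and 6–12 frame
miniatures for lifecycle and contract tests; the estimator benchmark is
the 100-frame sinusoid. These sizes put every quantitative check within a
few seconds while keeping the per-cell geometry (area, spacing, motion,
dropout) at the scale of the real experiments.

## Known limitations

* Association is greedy and per-cell (no global assignment); crossing or
  touching cells can momentarily merge into one component, and both tracks
  then follow the merged blob.
* OFFLINE is irreversible by design; a cell that recovers fluorescence
  after RL missing frames must be re-selected as a new track.
* The ratio is formed from index-paired frames; no temporal interpolation
  compensates the alternation of the excitation filters.
* No background subtraction precedes the ratio, and ratio values are not
  converted to absolute Ca²⁺ concentrations.
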