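# fura2track

Automated extraction of intracellular calcium profiles (CPs) from
dual-wavelength Fura-2 fluorescence image sequences of endothelial
monolayers.

Experiments on in situ endothelium record two 8-bit TIFF sequences, one per
excitation wavelength (340 nm and 380 nm, emission at 510 nm, one ratio
pair every T = 3 s). The pixelwise ratio R = I₃₄₀ / I₃₈₀ rises with
intracellular Ca²⁺, and the CP of a cell is the mean ratio inside a square
region of interest (ROI) around its nucleus, frame by frame. Cells move —
smooth-muscle contraction under agonists such as ATP, or outright
displacement after mechanical injury — so a fixed ROI corrupts the signal.
This package automates the whole chain: segmentation of every cell,
tracking of each ROI across the sequence, and profile extraction, for
hundreds of cells at once.

## Method

1. **Calibration** — from a few user-selected cell ROI areas, the
   processing window side is w = [a·√µ_areas] (a = 2 by default, the value
   that minimizes segmentation error against expert masks).
2. **Segmentation** (on the 340-nm channel) — median filter (window w/8),
   linear histogram stretch, then Niblack local thresholding
   T(x, y) = m(x, y) + k_T·s(x, y) with k_T = 1, where m and s are the
   windowed mean and standard deviation computed in O(1) per pixel with
   integral images; binary opening (disk r = 3), hole filling, dilation
   (disk r = 1); 8-connected labeling with centroids and areas.
3. **Tracking** — each selected cell carries its previous-frame component
   mask as a *kernel*; a logical AND with the current labeled frame yields
   candidate components. Ambiguous or empty intersections fall back on a
   Kalman prediction from a constant-acceleration motion model with white
   jerk process noise: state [x, ẋ, ẍ, y, ẏ, ÿ], Q = qᵀq with
   q = [T³σ_Jx/3, T²σ_Jx/2, Tσ_Jx, T³σ_Jy/3, T²σ_Jy/2, Tσ_Jy],
   R = diag(σ_x², σ_y²). A per-cell reliability counter counts consecutive
   missing frames; at the user-set reliability limit RL the track turns
   OFFLINE permanently (e.g. cells killed by the injuring micro-pipette).
4. **Extraction** — the ROI is re-centered on the tracked centroid each
   frame and the CP sampled from the ratio frame; the tracked-cell density
   ρᵢ = 100 · (ONLINE cells) / (binary objects) summarizes performance.

A fully specified synthetic module (`fura2track.synthetic`) generates
dual-wavelength phantoms and the deterministic sinusoid trajectory used to
benchmark the estimator, with exact ground truth for every stage.

## Worked example

```python
import numpy as np
from fura2track import (
    PhantomSpec, SegmentationParams, TrackingConfig, compute_window_size,
    gen_phantom, make_ratio_sequence, segment_sequence, run_tracking, summarize,
)

res = gen_phantom(PhantomSpec(shape=(256, 256), n_frames=50, n_cells=30,
                              motion_sd=0.5, seed=7))
w = compute_window_size([np.pi * r * r for r in res.radii], a=2.0)
params = SegmentationParams(w=w)
ratio = make_ratio_sequence(res.seq340, res.seq380)
labeled = segment_sequence(res.seq340, params)
out = run_tracking(labeled, ratio, selections="all", params=params,
                   config=TrackingConfig(rl=3))
print(f"w = {w}, tracks = {len(out.tracks)}, "
      f"rho mean = {out.performance.rho_mean:.1f}%")
print(summarize(out.tracks).head(3).to_string(index=False))
```

prints

```
w = 20, tracks = 30, rho mean = 99.9%
cell_id  mean_cp  frames_found  frames_total  found_fraction final_status
   A001 1.181345            50            50             1.0       ONLINE
   A002 1.180806            50            50             1.0       ONLINE
   A003 1.182046            50            50             1.0       ONLINE
```

`w = 20` is the calibrated window for ~100 px² cells; every cell is found
on every frame (ρ̄ ≈ 100%; it dips below only where two drifting cells
momentarily merge into one binary object), and each mean CP ≈ 1.18 matches
the time average (1.175) of the biphasic calcium waveform the phantom
embeds in its 340/380 ratio.

The same pipeline is available from the shell:

```bash
fura2track simulate phantom --out demo --seed 7
fura2track run --input-340 demo/phantom_340.tiff --input-380 demo/phantom_380.tiff \
               --w 20 --rl 3 --out demo_results
```

which writes `profiles.csv` (one row per cell and frame), `summary.csv`,
`rho.csv` and a `config.yaml` echo of the run.

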