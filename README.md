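# chemotrax

Automated tracking and motility analysis for time-lapse videos of cells
migrating through 3D collagen gels — the quantification half of a simple
3D chemotaxis assay. It is written for cell biologists who image
blob-like migrating cells (dendritic cells, MDA-MB-231 and similar) under
phase contrast and want per-cell speed, directionality and mean squared
displacement without manual clicking, plus a synthetic video generator
with known ground truth so every stage of the pipeline can be validated
quantitatively.

## What it computes

The pipeline runs four stages on a calibrated T×H×W grayscale TIFF stack
(pixel size in µm, frame interval in min):

1. **Preprocessing** — average-intensity time projection, subtracted from
   every frame (static collagen texture cancels, moving cells survive),
   followed by saturation-bounded linear contrast normalization (default
   0.1 % saturated pixels, per-frame histogram, output range [0, 255]).
2. **Detection** — scale-normalized Laplacian-of-Gaussian filtering,
   `R = −σ²·∇²(G_σ ∗ I)` with `σ = d/(2√2)` for blob diameter `d`
   (30 µm for DCs, 40 µm for MDA-MB-231), strict local maxima above a
   quality threshold (default 25), non-maximum suppression within `d/2`,
   and parabolic sub-pixel refinement.
3. **Tracking** — two-pass linear assignment ("simple LAP"): optimal
   frame-to-frame linking with squared-distance costs (max 50 µm), then
   gap closing between segment ends and starts (max 50 µm, max frame gap
   8). Every detection may instead start/end a track at 1.05× the largest
   feasible cost. No splitting or merging is modelled. Tracks can then be
   filtered by duration/quality (fixed or Otsu "auto" thresholds) and
   subsampled.
4. **Motility statistics** — per track: speed = path length / elapsed
   time (µm/min) and directionality ratio = |net displacement| / path
   length ∈ [0, 1]; per condition: time-averaged MSD
   `MSD(kΔt) = ⟨|r(t+kΔt) − r(t)|²⟩` ensemble-averaged across tracks with
   SEM, origin-aligned trajectory plots (≤ 256 series per plot), and a
   two-sided Mann–Whitney U comparison of conditions.

The `simulate` module generates matching synthetic videos: cells as
Gaussian bumps performing biased persistent random walks (bias weight 0 =
random motility, 1 = fully directed along the chemoattractant axis) with
hard-core volume exclusion, over an optional static collagen-like texture
with per-frame noise, plus the exact ground-truth trajectories.

## Worked example

```python
from chemotrax import (SimulationConfig, simulate_tracks, render_video,
                       PipelineConfig, run_pipeline)

cfg = SimulationConfig(seed=7, bias_weight=0.6, vanish_probability=0.02)
stack = render_video(simulate_tracks(cfg), cfg)          # 50 frames, 20 cells
result = run_pipeline(PipelineConfig(condition_label="ccl19"), stack, "demo_run")
summary = result["summary"]
print(summary.per_track.head(5).round(3).to_string(index=False))
```

```
 track_id  n_spots  duration_min  speed_um_per_min  directionality
        0       50          98.0             4.539           0.808
        1       50          98.0             4.614           0.896
        2       50          98.0             3.454           0.918
        3       50          98.0             3.099           0.355
        4       50          98.0             4.149           0.571
```

All 20 simulated cells are recovered as single 50-spot tracks spanning
98 min. Mean speed is 3.96 µm/min (the walkers move at ~5 µm/min along
their path; measured speed is slightly lower because sub-pixel detection
noise and interpolation across the occasional missed detection smooth the
path), and mean directionality 0.632 reflects the strong chemotactic bias
(an unbiased population of the same cells comes out near 0.5 under these
persistence settings, and a fully directed one near 1). `demo_run/`
contains the processed stack, spots/tracks tables (both the
spots-in-tracks and the concatenated three-column layout), an overlay
video, per-track and MSD CSVs, the origin-aligned trajectory plot and a
JSON run log with every parameter and per-stage count. The first MSD rows
grow ≈ quadratically with lag (79.7, 236.9, 506.8 µm² at 2, 4, 6 min), as
expected for directed motion.

The same workflow is scriptable from the shell:

```sh
chemotrax simulate sim.yaml fixture/
chemotrax run pipeline.yaml fixture/stack.tif out/
chemotrax compare out_a/tracks.csv out_b/tracks.csv --pixel-size 2 --frame-interval 2
```

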