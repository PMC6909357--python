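# Methods

This note documents the models and numerical choices behind chemotrax:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Coordinate and unit conventions

Positions are calibrated: `x = column × pixel_size`,
`y = row × pixel_size`, origin at the centre of the top-left pixel, y
increasing downward, frames 0-based. Lengths are µm, times minutes.
Calibration is always supplied explicitly (config or CLI) and wins over
any TIFF resolution tags — matching the usual practice of assigning image
properties manually before analysis. CSV output uses a fixed dialect
(comma, `.` decimal, LF, UTF-8) with 12-significant-digit floats, so
write→read round trips preserve coordinates to well beyond 9 digits.

## Preprocessing

A phase-contrast video of cells in collagen decomposes into a static
background (gel texture, illumination) plus moving cells. The
average-intensity time projection estimates the static part; subtracting
it leaves each cell's contrast minus its own 1/T contribution to the
projection (a bump of amplitude A that visits disjoint positions retains
A·(1−1/T)). Subtraction clips negatives by default, mirroring
unsigned-integer image arithmetic; a preserve-sign mode exists because
phase-contrast cells can be darker than background.

Contrast normalization finds per-frame cut values leaving
`saturated_fraction/2` of pixels in each tail (default 0.1 % total, split
equally — stated explicitly because recipes usually print only the
total), maps [low, high] linearly onto [0, 255] and clamps. A constant
frame maps to all zeros. The [0, 255] default keeps the detector's
quality threshold on a familiar 8-bit-like scale. Histogram equalization
is deliberately not implemented. Numerical detail: the projection is
computed as frame 0 plus the mean deviation from frame 0 — the same mean,
better conditioned — so a fully static scene preprocesses to exactly
zero rather than to amplified floating-point residue.

## Detection

The scale-normalized LoG response `−σ²·∇²(G_σ ∗ I)` of a bright blob of
diameter d peaks at its centre when `σ = d/(2√2)` (in 2D the response is
maximal for a disc of radius σ√2). The frame is demeaned before
filtering: the truncated discrete kernel does not sum exactly to zero, so
demeaning restores exact invariance to additive intensity offsets.
Filtering uses reflection padding; scales below 0.8 px are rejected as
unresolvable.

Candidate peaks are 8-neighborhood local maxima at or above the quality
threshold; maxima closer than d/2 are suppressed greedily, higher quality
first, ties to raster order for determinism. Quality is the response
value at the integer peak; since it follows the image intensity scale,
the default threshold of 25 is a calibration input valid for
[0, 255]-normalized frames, not a universal constant. Sub-pixel
refinement fits a separable 1D parabola through the three responses
around the peak, offset `(R₋−R₊)/(2(R₋−2R₀+R₊))` clamped to ±0.5 px; a
non-concave triple keeps the integer position. An optional "auto" mode
replaces the fixed threshold by Otsu's threshold on the frame's
local-maxima qualities — a documented, deterministic stand-in for
interactive auto-thresholding.

## Tracking

Both passes solve a linear assignment problem on an augmented square
matrix: link costs are squared Euclidean distances (the convention of LAP
trackers; printed parameters are distance *limits*), forbidden where the
distance exceeds the stage maximum, and every source/target can fall back
to a "death"/"birth" alternative costing `1.05 × max feasible cost`.
Without that alternative the problem is ill-posed (every detection would
be forced to link). The solution is a global optimum via the Hungarian
method, verified against exhaustive enumeration over all partial
matchings on small instances.

Gap closing assigns segment ends to later segment starts, feasible when
`1 ≤ Δframe ≤ 8` and distance ≤ 50 µm. "Max frame gap 8" permits a link
whose frame difference is exactly 8, i.e. up to 7 missing detections.
The gap cost is plain squared distance, not scaled by gap length — the
simplest rule consistent with the stated limits. Each end joins at most
one start: divisions and merges are not modelled, so a dividing cell
terminates its track. Ties between equal-cost optima are resolved by the
deterministic solver, so identical inputs always give identical tracks.

Track filtering keeps tracks at or above duration/mean-quality
thresholds; "auto" uses Otsu on the per-track feature distribution. The
keep-above direction for the quality filter is an interpretation (the
interactive tool does not document its direction); it matches the intent
of removing short, dim spurious tracks. Interior missing frames are
filled by linear interpolation (flagged `quality = 0`) before statistics,
restoring the uniform time base the statistics assume.

## Motility statistics

- **Speed** = total path length / elapsed time. Chosen because the data
  model is per-frame displacements on a uniform grid; equivalent to the
  time-weighted mean instantaneous speed.
- **Directionality ratio** = |net displacement| / path length, one value
  per track (the bar-plot convention); undefined (NaN, excluded) for
  zero-length paths. Removing interior points never decreases the ratio
  (triangle inequality) — which is exactly why manually clicked,
  effectively smoothed tracks report slightly higher directionality than
  automated tracking of the same cells.
- **MSD** uses overlapping (time-averaged) intervals per track, then
  averages across tracks per lag with SEM and track count. Lags beyond
  half the longest track are computed but flagged `low_confidence`
  (few independent intervals, high variance). Log-log slopes ≈ 1 / ≈ 2
  distinguish Brownian from ballistic motion.
- **Condition comparison**: two-sided Mann–Whitney U on per-track
  features, with group means ± SEM. The exact null distribution is used
  whenever the pooled sample is tie-free and min(n) ≤ 25 — small enough
  to enumerate instantly and necessary for exact p-values at typical
  30-cell comparisons — otherwise the normal approximation with tie
  correction.
- **Origin plots** refuse more than 256 trajectories unless overridden,
  mirroring the classic 256-series charting limit; the advice is to
  subsample (uniform without replacement, seeded, order-preserving).

## Synthetic data generator

The generator emulates a processed (background-subtracted) DC-like
acquisition; defaults: 20 cells, 256×256 px at 2 µm/px, 50 frames at
2 min, 30 µm blobs of amplitude 100 over Gaussian noise of SD 20 (peak
SNR 5), speeds ~N(5, 1) µm/min truncated at 0, heading diffusion SD
0.4 rad/step. The paper-agnostic choices (speeds, persistence) are
field-typical values for mature dendritic cells, not measured claims;
MDA-MB-231-like runs would use ~0.5 µm/min at 15 min intervals with
40 µm blobs.

Motion: headings evolve by wrapped Gaussian increments; the step
direction mixes the heading with the +x chemoattractant axis via
`bias_weight ∈ [0, 1]`; step length is `max(0, N(speed_mean, speed_sd))
× frame_interval`. Cells exclude volume: a step that would bring two
centres within one blob diameter re-draws its heading (stalling only
when fully surrounded), because cells in a gel cannot interpenetrate;
without exclusion, coalescing blobs make sub-pixel detection accuracy
unmeasurable. Trajectories reflect at a blob-radius inset of the field so
cells never leave view and all tracks span every frame — convenient for
statistics, at the cost of mild confinement; motion-statistics tests
therefore use physically large fields where reflections are negligible.
`vanish_probability` hides a cell from individual frames to create
detection gaps for gap-closing tests. Rendering adds a static smoothed-
noise collagen-like texture (optional), one isotropic Gaussian bump of SD
`blob_diameter/4` per rendered cell, and per-frame pixel noise, clipping
at zero. Trajectory and rendering randomness come from separate streams
of the same seed, so ground truth is independent of rendering options.

What the generator does **not** emulate: cell shape and deformation,
intensity variation between cells, collagen fiber structure beyond
smooth texture, z-drift and out-of-focus cells, divisions, and
photobleaching. Passing the validation suite therefore shows the
algorithmic chain is correct and accurate on blob-like data at realistic
SNR and density — it does not certify performance on any particular
microscope's raw data, where detector thresholds and blob diameters must
be re-tuned.

## Validation conditions and problem sizes

The test suite and `scripts/acceptance.py` use: 200 random assignment
instances up to 6×6 against exhaustive enumeration; the default 20-cell
fixture for detection accuracy (match radius = blob radius); 30 cells at
≥ 60 µm mutual separation with 5 % vanishing for tracking recovery —
60 µm mirrors the well-separated regime (steps < ½ nearest-neighbour
distance, spacing beyond the linking radius) in which identity
preservation is the meaningful claim; when cells approach within the
linking radius while detections drop out, capture of a neighbour is the
correct optimal-assignment behaviour, not a bug; 200-track ensembles of
101 frames for MSD slopes; 100 tracks per condition (bias 0 vs 0.5) for
the chemotaxis comparison; and weakly persistent walkers
(`persistence_sd = 1.5`) for the bias-monotonicity property, where the
bias effect is not confounded by already-saturated persistence.

## Known limitations

- Single-scale detection: cells far from the configured diameter are
  missed or mislocalized; particle size must be constant per experiment.
- The tracker has no motion model (no velocity prediction); very fast
  cells in dense fields can swap identities, bounded by the linking
  radius.
- 2D analysis of cells moving in a thin 3D slab: out-of-plane motion
  appears as speed fluctuation.
- MSD values at lags near the track length are noisy even with the
  low-confidence flag; directionality depends on track duration, so
  conditions should be compared at matched durations.
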