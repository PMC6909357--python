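"""Background subtraction and contrast normalization for time-lapse stacks.

The processing chain mirrors the standard recipe for phase-contrast
migration videos: (1) average-intensity projection over time, (2) pixelwise
subtraction of that projection from every frame — anything static, such as
the collagen texture, cancels while moving cells survive — and
(3) saturation-bounded linear contrast normalization, where a small
fraction of extreme pixels is allowed to clip so the bulk of the histogram
fills the output range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .stackio import CalibrationMetadata, ImageStack, read_stack, write_stack
import tifffile

__all__ = [
    "PreprocessParams",
    "average_projection",
    "subtract_background",
    "enhance_contrast",
    "preprocess_stack",
    "preprocess_batch",
]


@dataclass
class PreprocessParams:
    """Parameters of the preprocessing chain.

    saturated_fraction
        Total fraction of pixels allowed to saturate during normalization
        (default 0.001, i.e. 0.1 %), split equally between the low and high
        tails.
    per_frame_histogram
        Compute the cut values per frame (default) rather than from the
        whole stack's histogram.
    clip_negative
        Floor subtraction results at 0, mirroring unsigned-integer image
        arithmetic.  Disable to keep cells darker than background.
    output_range
        Intensity interval the normalized data is mapped into.  The default
        [0, 255] keeps downstream detector thresholds on a familiar scale.
    """

    saturated_fraction: float = 0.001
    per_frame_histogram: bool = True
    clip_negative: bool = True
    output_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.saturated_fraction < 0.5):
            raise ValueError(
                f"saturated_fraction must be in [0, 0.5), got {self.saturated_fraction}"
            )
        lo, hi = self.output_range
        if not (hi > lo):
            raise ValueError(f"output_range must be increasing, got {self.output_range}")


def average_projection(stack: ImageStack) -> np.ndarray:
    """Pixel-wise arithmetic mean over all frames, in floating point.

    Computed as frame 0 plus the mean deviation from frame 0: identical in
    exact arithmetic, but better conditioned — in particular, a static
    scene projects to frame 0 bit-exactly, so subtraction cancels it to
    exactly zero.
    """
    f0 = stack.frames[0]
    return f0 + (stack.frames - f0).mean(axis=0)


def subtract_background(
    stack: ImageStack,
    projection: np.ndarray,
    params: PreprocessParams | None = None,
) -> ImageStack:
    """Subtract a 2D background image from every frame."""
    params = params or PreprocessParams()
    projection = np.asarray(projection, dtype=np.float64)
    if projection.shape != stack.frames.shape[1:]:
        raise ValueError(
            f"projection shape {projection.shape} does not match frames "
            f"{stack.frames.shape[1:]}"
        )
    out = stack.frames - projection[None, :, :]
    if params.clip_negative:
        out = np.clip(out, 0.0, None)
    return ImageStack(frames=out, calibration=stack.calibration)


def _cut_values(values: np.ndarray, saturated_fraction: float) -> tuple[float, float]:
    """Low/high cut values leaving ``saturated_fraction/2`` of pixels in
    each tail."""
    v = np.sort(values, axis=None)
    n = v.size
    k = int(n * saturated_fraction / 2.0)
    k = min(k, (n - 1) // 2)
    return float(v[k]), float(v[n - 1 - k])


def enhance_contrast(stack: ImageStack, params: PreprocessParams | None = None) -> ImageStack:
    """Saturation-bounded linear normalization into ``output_range``.

    Per frame (or from the stack histogram when ``per_frame_histogram`` is
    off): find cut values so that half of ``saturated_fraction`` of the
    pixels lie below/above them, map [low, high] linearly onto the output
    range, and clamp.  A constant frame has no contrast to stretch and maps
    to all zeros.
    """
    params = params or PreprocessParams()
    lo_out, hi_out = params.output_range
    frames = stack.frames
    out = np.empty_like(frames)

    if params.per_frame_histogram:
        cuts = [_cut_values(f, params.saturated_fraction) for f in frames]
    else:
        cuts = [_cut_values(frames, params.saturated_fraction)] * len(frames)

    for i, (f, (low, high)) in enumerate(zip(frames, cuts)):
        if high <= low:
            out[i] = 0.0
        else:
            scaled = (f - low) / (high - low) * (hi_out - lo_out) + lo_out
            out[i] = np.clip(scaled, lo_out, hi_out)
    return ImageStack(frames=out, calibration=stack.calibration)


def preprocess_stack(stack: ImageStack, params: PreprocessParams | None = None) -> ImageStack:
    """Full chain: projection -> subtraction -> contrast normalization."""
    params = params or PreprocessParams()
    proj = average_projection(stack)
    sub = subtract_background(stack, proj, params)
    return enhance_contrast(sub, params)


def preprocess_batch(
    in_dir: str | Path,
    projection_dir: str | Path,
    out_dir: str | Path,
    calibration: CalibrationMetadata,
    params: PreprocessParams | None = None,
) -> list[Path]:
    """Process every TIFF stack in a folder.

    Mirrors the batch-macro flow: an input folder of raw videos, one output
    folder receiving the time projections, and one receiving the processed
    (background-subtracted, normalized) stacks.  Returns the processed
    paths.
    """
    in_dir, projection_dir, out_dir = Path(in_dir), Path(projection_dir), Path(out_dir)
    projection_dir.mkdir(parents=True, exist_ok=True)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or PreprocessParams()
    written = []
    for path in sorted(in_dir.iterdir()):
        if path.suffix.lower() not in (".tif", ".tiff"):
            continue
        stack = read_stack(path, calibration)
        proj = average_projection(stack)
        tifffile.imwrite(
            projection_dir / path.name, proj.astype(np.float32), photometric="minisblack"
        )
        processed = enhance_contrast(subtract_background(stack, proj, params), params)
        written.append(write_stack(processed, out_dir / path.name))
    return written
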