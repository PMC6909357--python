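"""Laplacian-of-Gaussian cell detection with sub-pixel localization.

Cells appear in processed phase-contrast frames as bright blobs of roughly
known diameter.  A scale-normalized LoG filter,

    R = -sigma^2 * Laplacian(G_sigma * frame),

turns each blob into a positive peak whose height ("quality") is invariant
to additive offsets and proportional to contrast.  The filter scale is
``sigma = blob_diameter / (2 sqrt 2)``: in 2D the scale-normalized LoG
responds maximally to a disc of radius ``sigma * sqrt 2``, so this choice
matches a blob of the stated diameter.

Peaks are strict 8-neighborhood local maxima above a quality threshold;
maxima closer than half a blob diameter are suppressed in favor of the
stronger one, and surviving peaks are refined to sub-pixel precision by a
separable 1D parabolic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .stackio import CalibrationMetadata, ImageStack, Spot

__all__ = [
    "DetectionParams",
    "log_response",
    "detect_spots",
    "refine_subpixel",
]


@dataclass
class DetectionParams:
    """Detector configuration.

    blob_diameter
        Expected cell diameter in um (30 for dendritic cells, 40 for
        MDA-MB-231-like cells).
    quality_threshold
        Minimum LoG response at a peak.  The default of 25 assumes frames
        normalized into [0, 255]; the quality scale follows the image
        intensity scale, so this is a calibration input, not a constant.
    subpixel
        Refine peak positions by parabolic interpolation.
    median_filter
        Apply a 3x3 median filter before the LoG (off by default).
    auto_quality
        Replace the fixed threshold by Otsu's threshold computed on the
        frame's local-maxima qualities.
    """

    blob_diameter: float = 30.0
    quality_threshold: float = 25.0
    subpixel: bool = True
    median_filter: bool = False
    auto_quality: bool = False

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError(
                f"quality_threshold must be >= 0, got {self.quality_threshold}"
            )


def log_sigma_px(blob_diameter: float, calibration: CalibrationMetadata) -> float:
    """LoG scale in pixels for a given blob diameter in um."""
    return blob_diameter / (2.0 * np.sqrt(2.0)) / calibration.pixel_size


def log_response(
    frame: np.ndarray,
    blob_diameter: float,
    calibration: CalibrationMetadata,
) -> np.ndarray:
    """Scale-normalized negative LoG response; bright blobs give positive
    peaks.  Borders are handled by reflection padding."""
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    sigma = log_sigma_px(blob_diameter, calibration)
    if sigma < 0.8:
        raise ValueError(
            f"LoG scale {sigma:.3f} px is below 0.8 px: blob unresolvable at "
            f"this pixel size"
        )
    # The truncated discrete kernel does not sum exactly to zero, so a
    # constant offset would leak through; demeaning restores exact
    # invariance to additive offsets.
    return -(sigma**2) * ndi.gaussian_laplace(
        frame - frame.mean(), sigma, mode="reflect"
    )


def _local_maxima(response: np.ndarray, threshold: float) -> np.ndarray:
    """(n, 2) array of (row, col) local maxima with response >= threshold.

    A pixel qualifies when it is >= all 8 neighbors; plateau ties are
    resolved later by distance suppression, where raster order wins.
    """
    footprint = np.ones((3, 3), dtype=bool)
    mx = ndi.maximum_filter(response, footprint=footprint, mode="reflect")
    cand = (response >= mx) & (response >= threshold)
    return np.argwhere(cand)


def _suppress(
    peaks: np.ndarray, qualities: np.ndarray, min_dist_px: float
) -> list[int]:
    """Greedy non-maximum suppression; higher quality wins, ties go to
    raster order (smaller row, then column)."""
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-qualities[i], peaks[i][0], peaks[i][1]),
    )
    kept: list[int] = []
    d2 = min_dist_px**2
    for i in order:
        r, c = peaks[i]
        if all((r - peaks[j][0]) ** 2 + (c - peaks[j][1]) ** 2 >= d2 for j in kept):
            kept.append(i)
    return kept


def refine_subpixel(
    response: np.ndarray,
    peak: tuple[int, int],
    calibration: CalibrationMetadata,
) -> tuple[float, float]:
    """Parabolic sub-pixel refinement of an interior peak.

    Per axis, a parabola through the three responses centred at the peak
    gives the offset ``(R_minus - R_plus) / (2 (R_minus - 2 R_0 + R_plus))``,
    clamped to [-0.5, 0.5] px.  A non-concave triple (degenerate curvature)
    leaves the axis offset at 0.  Returns ``(x, y)`` in um.
    """
    r, c = peak
    h, w = response.shape
    if not (0 < r < h - 1 and 0 < c < w - 1):
        raise ValueError(f"peak {peak} lies on the image border")

    def axis_offset(m: float, o: float, p_: float) -> float:
        denom = m - 2.0 * o + p_
        if denom >= 0:
            return 0.0
        return float(np.clip((m - p_) / (2.0 * denom), -0.5, 0.5))

    dy = axis_offset(response[r - 1, c], response[r, c], response[r + 1, c])
    dx = axis_offset(response[r, c - 1], response[r, c], response[r, c + 1])
    p = calibration.pixel_size
    return (c + dx) * p, (r + dy) * p


def detect_spots(stack: ImageStack, params: DetectionParams) -> list[Spot]:
    """Detect cell centers in every frame of a (preprocessed) stack."""
    cal = stack.calibration
    if params.blob_diameter <= 2 * cal.pixel_size:
        raise ValueError(
            f"blob_diameter {params.blob_diameter} um must exceed 2 px "
            f"({2 * cal.pixel_size} um)"
        )
    p = cal.pixel_size
    min_dist_px = (params.blob_diameter / 2.0) / p
    spots: list[Spot] = []
    for t, frame in enumerate(stack.frames):
        if params.median_filter:
            frame = ndi.median_filter(frame, size=3, mode="reflect")
        resp = log_response(frame, params.blob_diameter, cal)

        if params.auto_quality:
            maxima = _local_maxima(resp, 0.0)
            quals = resp[maxima[:, 0], maxima[:, 1]] if len(maxima) else np.array([])
            threshold = _otsu_or_min(quals)
        else:
            threshold = params.quality_threshold
        peaks = _local_maxima(resp, threshold)
        if len(peaks) == 0:
            continue
        quals = resp[peaks[:, 0], peaks[:, 1]]
        for i in _suppress(peaks, quals, min_dist_px):
            r, c = int(peaks[i][0]), int(peaks[i][1])
            h, w = resp.shape
            if params.subpixel and 0 < r < h - 1 and 0 < c < w - 1:
                x, y = refine_subpixel(resp, (r, c), cal)
            else:
                x, y = c * p, r * p
            spots.append(Spot(frame=t, x=x, y=y, quality=float(quals[i])))
    return spots


def _otsu_or_min(values: np.ndarray) -> float:
    """Otsu's threshold on a 1D sample; degenerate samples keep everything."""
    if values.size < 2 or np.ptp(values) == 0:
        return float(values.min()) if values.size else 0.0
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))
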