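"""Calibrated image stacks, trajectory tables, and track overlays.

The workflow's spatial unit is the micrometre and its temporal unit the
minute.  A :class:`CalibrationMetadata` attached to every stack converts
between pixel indices and physical coordinates; the convention used
throughout the package is

    x = column_index * pixel_size,   y = row_index * pixel_size,

with the origin at the centre of the top-left pixel and y increasing
downward.  Frame indices are 0-based.

Two trajectory-table layouts are supported:

``spots_in_tracks``
    One row per detection with columns
    ``TRACK_ID,SPOT_ID,FRAME,POSITION_X,POSITION_Y,QUALITY`` — the layout
    single-particle trackers export for downstream spreadsheet analysis.

``diper``
    Three columns ``FRAME,POSITION_X,POSITION_Y`` with the trajectories of
    all cells concatenated one after the other without blank rows, preceded
    by the total track count.  This is the concatenated layout expected by
    DiPer-style motility quantification macros.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibrationMetadata",
    "ImageStack",
    "Spot",
    "Track",
    "read_stack",
    "write_stack",
    "write_spots_table",
    "read_spots_table",
    "render_overlay",
    "track_color",
]

# Coordinates survive a CSV round trip to well beyond 9 significant digits.
_FLOAT_FMT = "%.12g"

SPOTS_IN_TRACKS_COLUMNS = (
    "TRACK_ID",
    "SPOT_ID",
    "FRAME",
    "POSITION_X",
    "POSITION_Y",
    "QUALITY",
)
DIPER_COLUMNS = ("FRAME", "POSITION_X", "POSITION_Y")


@dataclass(frozen=True)
class CalibrationMetadata:
    """Spatial and temporal calibration of a time-lapse acquisition.

    Parameters
    ----------
    pixel_size : float
        Physical size of one pixel, in micrometres per pixel.
    frame_interval : float
        Time between consecutive frames, in minutes.
    length_unit : str
        Label for the length unit (display only).
    """

    pixel_size: float
    frame_interval: float
    length_unit: str = "um"

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_interval > 0):
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )


@dataclass
class ImageStack:
    """A T x H x W grayscale time-lapse with attached calibration."""

    frames: np.ndarray
    calibration: CalibrationMetadata

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a T x H x W array, got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape
        if t < 2:
            raise ValueError(f"stack must have at least 2 frames, got {t}")
        if h < 16 or w < 16:
            raise ValueError(f"frame size must be at least 16 x 16, got {h} x {w}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stack contains non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def bounds_um(self) -> tuple[float, float]:
        """(x_max, y_max) of valid coordinates, in micrometres."""
        _, h, w = self.frames.shape
        p = self.calibration.pixel_size
        return (w - 1) * p, (h - 1) * p


@dataclass(frozen=True)
class Spot:
    """A single detection: frame index and calibrated position in um."""

    frame: int
    x: float
    y: float
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")
        if not np.isfinite([self.x, self.y, self.quality]).all():
            raise ValueError("spot coordinates/quality must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Track:
    """An ordered sequence of spots with strictly increasing frames."""

    track_id: int
    spots: list[Spot]

    def __post_init__(self) -> None:
        if len(self.spots) < 2:
            raise ValueError(
                f"track {self.track_id} needs >= 2 spots, got {len(self.spots)}"
            )
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(
                f"track {self.track_id}: frames must be strictly increasing"
            )

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in um."""
        return np.array([[s.x, s.y] for s in self.spots])

    @property
    def duration_frames(self) -> int:
        return self.spots[-1].frame - self.spots[0].frame

    def mean_quality(self) -> float:
        return float(np.mean([s.quality for s in self.spots]))


# ---------------------------------------------------------------------------
# Image stack I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, calibration: CalibrationMetadata) -> ImageStack:
    """Read a multi-page grayscale TIFF time-lapse.

    Intensities are converted to float64; page order is preserved.  The
    supplied calibration always wins over whatever resolution tags the file
    may carry, mirroring workflows where pixel size and frame interval are
    assigned manually at analysis time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError(
            f"{path.name}: a time-lapse needs at least 2 pages, got a single image"
        )
    if arr.ndim != 3:
        raise ValueError(
            f"{path.name}: expected grayscale pages, got page shape {arr.shape[1:]}"
        )
    return ImageStack(frames=arr.astype(np.float64), calibration=calibration)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Trajectory tables
# ---------------------------------------------------------------------------

def write_spots_table(
    tracks: list[Track],
    path: str | Path,
    layout: str = "spots_in_tracks",
) -> Path:
    """Write tracks to CSV in one of the two supported layouts.

    I/O is lossless: rows are written as-is, gaps in a track are neither
    filled nor flagged.  The CSV dialect is fixed (comma separator, ``.``
    decimal, LF line endings, UTF-8) for bit-exact reproducibility.
    """
    if not tracks:
        raise ValueError("cannot write an empty track list")
    if layout not in ("spots_in_tracks", "diper"):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    ordered = sorted(tracks, key=lambda t: t.track_id)

    buf = io.StringIO()
    if layout == "spots_in_tracks":
        buf.write(",".join(SPOTS_IN_TRACKS_COLUMNS) + "\n")
        spot_id = 0
        for tr in ordered:
            for s in sorted(tr.spots, key=lambda s: s.frame):
                buf.write(
                    "%d,%d,%d,%s,%s,%s\n"
                    % (
                        tr.track_id,
                        spot_id,
                        s.frame,
                        _FLOAT_FMT % s.x,
                        _FLOAT_FMT % s.y,
                        _FLOAT_FMT % s.quality,
                    )
                )
                spot_id += 1
    else:
        buf.write("TOTAL_TRACKS,%d\n" % len(ordered))
        buf.write(",".join(DIPER_COLUMNS) + "\n")
        for tr in ordered:
            for s in sorted(tr.spots, key=lambda s: s.frame):
                buf.write(
                    "%d,%s,%s\n" % (s.frame, _FLOAT_FMT % s.x, _FLOAT_FMT % s.y)
                )
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")
    return path


def read_spots_table(path: str | Path) -> list[Track]:
    """Read a trajectory table, auto-detecting its layout from the header.

    For the spots-in-tracks layout, rows may arrive in any order; they are
    sorted by (track, frame) before reconstruction, and a duplicated frame
    within a track is reported with its row number.  For the concatenated
    layout, a new track starts wherever the frame number fails to increase.
    Extra columns beyond the canonical six are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory table not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    fields = [f.strip().upper() for f in first.split(",")]

    if fields[0] == "TOTAL_TRACKS":
        declared = int(fields[1])
        df = pd.read_csv(path, skiprows=1)
        df.columns = [c.strip().upper() for c in df.columns]
        tracks = _tracks_from_diper(df)
        if len(tracks) != declared:
            raise ValueError(
                f"{path.name}: declared {declared} tracks but found {len(tracks)}"
            )
        return tracks

    if set(SPOTS_IN_TRACKS_COLUMNS).issubset(fields):
        df = pd.read_csv(path)
        df.columns = [c.strip().upper() for c in df.columns]
        return _tracks_from_spots_in_tracks(df)

    if set(DIPER_COLUMNS).issubset(fields):
        df = pd.read_csv(path)
        df.columns = [c.strip().upper() for c in df.columns]
        return _tracks_from_diper(df)

    raise ValueError(f"{path.name}: unrecognized header {first!r}")


def _tracks_from_spots_in_tracks(df: pd.DataFrame) -> list[Track]:
    df = df.sort_values(["TRACK_ID", "FRAME"], kind="stable")
    tracks = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        frames = grp["FRAME"].to_numpy(dtype=int)
        dup = np.nonzero(np.diff(frames) <= 0)[0]
        if dup.size:
            row = grp.index[dup[0] + 1]
            raise ValueError(
                f"track {tid}: non-monotone frame sequence at input row {row}"
            )
        spots = [
            Spot(frame=int(r.FRAME), x=float(r.POSITION_X),
                 y=float(r.POSITION_Y), quality=float(r.QUALITY))
            for r in grp.itertuples()
        ]
        tracks.append(Track(track_id=int(tid), spots=spots))
    return tracks


def _tracks_from_diper(df: pd.DataFrame) -> list[Track]:
    frames = df["FRAME"].to_numpy(dtype=int)
    # A trajectory block ends where the frame number stops increasing.
    breaks = np.nonzero(np.diff(frames) <= 0)[0] + 1
    starts = np.concatenate(([0], breaks))
    stops = np.concatenate((breaks, [len(df)]))
    tracks = []
    for tid, (a, b) in enumerate(zip(starts, stops)):
        block = df.iloc[a:b]
        spots = [
            Spot(frame=int(r.FRAME), x=float(r.POSITION_X),
                 y=float(r.POSITION_Y))
            for r in block.itertuples()
        ]
        tracks.append(Track(track_id=tid, spots=spots))
    return tracks


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

# 20 well-separated RGB colors, cycled deterministically by track id.
_PALETTE = np.array(
    [
        (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
        (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
        (210, 245, 60), (250, 190, 190), (0, 128, 128), (230, 190, 255),
        (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
        (128, 128, 0), (255, 215, 180), (0, 0, 128), (128, 128, 128),
    ],
    dtype=np.uint8,
)


def track_color(track_id: int) -> tuple[int, int, int]:
    """Deterministic RGB color for a track id (pure function)."""
    return tuple(int(c) for c in _PALETTE[track_id % len(_PALETTE)])


def render_overlay(
    stack: ImageStack, tracks: list[Track], path: str | Path
) -> Path:
    """Render tracks over the video as a multi-page RGB TIFF.

    Frame ``t`` shows, for every track, the polyline through its spots up to
    and including frame ``t``, so each trajectory grows as the video plays.
    """
    from skimage.draw import line as draw_line

    p = stack.calibration.pixel_size
    x_max, y_max = stack.bounds_um()
    for tr in tracks:
        pos = tr.positions
        if (pos < -1e-9).any() or (pos[:, 0] > x_max + 1e-9).any() or (
            pos[:, 1] > y_max + 1e-9
        ).any():
            raise ValueError(
                f"track {tr.track_id} has coordinates outside the image bounds"
            )

    frames = stack.frames
    lo, hi = frames.min(), frames.max()
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    base = ((frames - lo) * scale).astype(np.uint8)
    rgb = np.repeat(base[..., None], 3, axis=-1)

    t_count, h, w = frames.shape
    for t in range(t_count):
        img = rgb[t]
        for tr in tracks:
            color = track_color(tr.track_id)
            pts = [
                (int(round(s.y / p)), int(round(s.x / p)))
                for s in tr.spots
                if s.frame <= t
            ]
            for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
                rr, cc = draw_line(r0, c0, r1, c1)
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                img[rr[ok], cc[ok]] = color
            if pts:
                r, c = pts[-1]
                if 0 <= r < h and 0 <= c < w:
                    img[r, c] = color

    path = Path(path)
    tifffile.imwrite(path, rgb, photometric="rgb")
    return path
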