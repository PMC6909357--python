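"""Trajectory motility statistics: speed, directionality ratio, MSD.

Definitions used throughout:

speed
    Total path length divided by elapsed time (um/min) — equivalently the
    time-weighted mean of the instantaneous speeds on a uniform time grid.

directionality ratio
    Net displacement divided by total path length, one value per track;
    1 for perfectly straight motion, approaching 0 for confined or random
    motion.  Removing interior points of a trajectory can only shorten the
    measured path (triangle inequality) while keeping the endpoints, so
    any smoothing or coarser sampling of the same motion can only raise
    this ratio — the reason manually clicked (straightened) tracks report
    slightly higher directionality than automated tracking of the same
    cells.

MSD
    Time-averaged mean squared displacement per track over overlapping
    intervals, MSD(k dt) = <|r(t + k) - r(t)|^2>_t, ensemble-averaged
    across tracks per lag with SEM and track count.  On log-log axes the
    slope is ~1 for Brownian and ~2 for ballistic motion.

Gap-closed tracks miss interior frames; :func:`regularize_track` restores a
uniform time base by linear interpolation before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stackio import CalibrationMetadata, Spot, Track

__all__ = [
    "MotilitySummary",
    "MannWhitneyResult",
    "regularize_track",
    "track_speed",
    "directionality_ratio",
    "msd",
    "plot_at_origin",
    "compare_conditions",
    "summarize",
]

#: Largest number of trajectories a single origin plot will draw without an
#: explicit override (classic charting limit of 256 series per plot).
MAX_PLOT_SERIES = 256


@dataclass
class MotilitySummary:
    """Per-track statistics plus the ensemble MSD curve for one condition."""

    per_track: pd.DataFrame  # track_id, n_spots, duration_min, speed_um_per_min, directionality
    msd: pd.DataFrame  # lag_min, msd_um2, sem_um2, n_tracks, low_confidence
    condition_label: str
    tracks: list[Track] | None = None

    def feature(self, name: str) -> np.ndarray:
        col = {"speed": "speed_um_per_min", "directionality": "directionality"}[name]
        vals = self.per_track[col].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int


def regularize_track(
    track: Track, calibration: CalibrationMetadata | None = None
) -> Track:
    """Fill missing interior frames by linear interpolation.

    Interpolated spots carry ``quality = 0`` as a flag; tracks without gaps
    are returned unchanged.
    """
    frames = track.frames
    if np.all(np.diff(frames) == 1):
        return track
    full = np.arange(frames[0], frames[-1] + 1)
    pos = track.positions
    x = np.interp(full, frames, pos[:, 0])
    y = np.interp(full, frames, pos[:, 1])
    observed = {s.frame: s for s in track.spots}
    spots = [
        observed[f] if f in observed else Spot(frame=int(f), x=float(xi), y=float(yi), quality=0.0)
        for f, xi, yi in zip(full, x, y)
    ]
    return Track(track_id=track.track_id, spots=spots)


def _path_length(track: Track) -> float:
    steps = np.diff(track.positions, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def track_speed(track: Track, calibration: CalibrationMetadata) -> float:
    """Mean speed in um/min: total path length over elapsed time."""
    if len(track.spots) < 2:
        raise ValueError("speed needs at least 2 spots")
    duration_min = track.duration_frames * calibration.frame_interval
    return _path_length(track) / duration_min


def directionality_ratio(track: Track) -> float:
    """Net displacement over path length; NaN for a zero-length path."""
    path = _path_length(track)
    if path == 0:
        return float("nan")
    net = float(np.hypot(*(track.positions[-1] - track.positions[0])))
    return net / path


def track_msd(track: Track, calibration: CalibrationMetadata) -> np.ndarray:
    """Time-averaged MSD of one regularized track for lags 1..n-1 frames."""
    pos = track.positions
    n = len(pos)
    out = np.empty(n - 1)
    for k in range(1, n):
        d = pos[k:] - pos[:-k]
        out[k - 1] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    return out


def msd(tracks: list[Track], calibration: CalibrationMetadata) -> pd.DataFrame:
    """Ensemble MSD curve across tracks.

    Each track contributes its time-averaged MSD at every lag it supports;
    the ensemble value per lag is the mean across contributing tracks with
    its SEM and count (``n_tracks`` is non-increasing with lag).  Lags
    beyond half the longest track are kept but flagged ``low_confidence``
    — time averaging leaves few independent intervals there.
    """
    if not tracks:
        raise ValueError("msd needs at least one track")
    dt = calibration.frame_interval
    per_track = [track_msd(regularize_track(t), calibration) for t in tracks]
    max_lag = max(len(m) for m in per_track)
    rows = [
        {"lag_min": 0.0, "msd_um2": 0.0, "sem_um2": 0.0,
         "n_tracks": len(tracks), "low_confidence": False}
    ]
    for k in range(1, max_lag + 1):
        vals = np.array([m[k - 1] for m in per_track if len(m) >= k])
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "lag_min": k * dt,
                "msd_um2": float(vals.mean()),
                "sem_um2": sem,
                "n_tracks": int(len(vals)),
                "low_confidence": k > max_lag / 2,
            }
        )
    return pd.DataFrame(rows)


def plot_at_origin(
    tracks: list[Track],
    out: str | Path,
    override_series_limit: bool = False,
) -> Path:
    """Overplot all trajectories translated to start at the origin.

    Axes are equal; each track keeps its deterministic color.  More than
    256 trajectories are refused unless ``override_series_limit`` is set —
    subsample first (see :func:`chemotrax.track.subsample_tracks`).
    """
    if not tracks:
        raise ValueError("nothing to plot")
    if len(tracks) > MAX_PLOT_SERIES and not override_series_limit:
        raise ValueError(
            f"{len(tracks)} trajectories exceed the {MAX_PLOT_SERIES}-series "
            "plot limit; subsample first (chemotrax.track.subsample_tracks) "
            "or pass override_series_limit=True"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stackio import track_color

    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in tracks:
        pos = tr.positions - tr.positions[0]
        color = tuple(c / 255.0 for c in track_color(tr.track_id))
        ax.plot(pos[:, 0], pos[:, 1], lw=0.8, color=color)
    ax.set_aspect("equal")
    ax.axhline(0, color="0.85", lw=0.5)
    ax.axvline(0, color="0.85", lw=0.5)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{len(tracks)} trajectories, origin-aligned")
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def compare_conditions(
    a: MotilitySummary, b: MotilitySummary, feature: str = "directionality"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between conditions on a per-track
    feature ("speed" or "directionality").

    The exact null distribution is used whenever the samples are tie-free
    and small enough to enumerate cheaply (min(n) <= 25); otherwise the
    normal approximation with tie correction applies.  Group means +/- SEM
    accompany the test, matching the usual bar-plot presentation.
    """
    xa, xb = a.feature(feature), b.feature(feature)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 tracks per condition")
    pooled = np.concatenate([xa, xb])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and min(len(xa), len(xb)) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        mean_a=float(xa.mean()),
        sem_a=float(xa.std(ddof=1) / np.sqrt(len(xa))) if len(xa) > 1 else 0.0,
        n_a=len(xa),
        mean_b=float(xb.mean()),
        sem_b=float(xb.std(ddof=1) / np.sqrt(len(xb))) if len(xb) > 1 else 0.0,
        n_b=len(xb),
    )


def summarize(
    tracks: list[Track],
    calibration: CalibrationMetadata,
    label: str = "",
    out_dir: str | Path | None = None,
) -> MotilitySummary:
    """Regularize tracks and compute the full per-condition summary.

    Tracks with zero path length have undefined directionality and carry
    NaN there; they are excluded from feature comparisons.  When
    ``out_dir`` is given, per-track and MSD tables are written as CSV.
    """
    if not tracks:
        raise ValueError("no usable tracks")
    reg = [regularize_track(t, calibration) for t in tracks]
    rows = []
    for t in reg:
        rows.append(
            {
                "track_id": t.track_id,
                "n_spots": len(t.spots),
                "duration_min": t.duration_frames * calibration.frame_interval,
                "speed_um_per_min": track_speed(t, calibration),
                "directionality": directionality_ratio(t),
            }
        )
    per_track = pd.DataFrame(rows)
    msd_table = msd(reg, calibration)
    summary = MotilitySummary(
        per_track=per_track, msd=msd_table, condition_label=label, tracks=reg
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = f"_{label}" if label else ""
        per_track.to_csv(out_dir / f"per_track{tag}.csv", index=False)
        msd_table.to_csv(out_dir / f"msd{tag}.csv", index=False)
    return summary
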