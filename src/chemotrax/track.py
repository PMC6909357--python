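"""Two-pass linear-assignment tracking with gap closing.

Pass one links detections between consecutive frames by solving, per frame
pair, a linear assignment problem whose link cost is the squared Euclidean
distance (um^2); links longer than ``linking_max_distance`` are forbidden.
Every detection may alternatively start or end a track ("birth"/"death") at
a cost of ``alternative_cost_factor`` times the largest feasible link cost
in the matrix — without this alternative the assignment problem would force
every detection to link.

Pass two reconnects track segments across missed detections: segment ends
are assigned to later segment starts, feasible when the frame difference is
between 1 and ``gap_closing_max_frame_gap`` (a gap of 8 frames, i.e. up to
7 missing detections, is allowed at the default) and the distance is within
``gap_closing_max_distance``.  No splitting or merging is modelled: each
end joins at most one start, so a dividing cell simply terminates its
track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .stackio import Spot, Track

__all__ = [
    "LinkingParams",
    "TrackFilter",
    "AssignmentResult",
    "solve_assignment",
    "link_frames",
    "close_gaps",
    "filter_tracks",
    "subsample_tracks",
]


@dataclass
class LinkingParams:
    """Tracker configuration; distances in um, gaps in frames."""

    linking_max_distance: float = 50.0
    gap_closing_max_distance: float = 50.0
    gap_closing_max_frame_gap: int = 8
    alternative_cost_factor: float = 1.05

    def __post_init__(self) -> None:
        if self.linking_max_distance <= 0 or self.gap_closing_max_distance <= 0:
            raise ValueError("distance limits must be > 0")
        if self.gap_closing_max_frame_gap < 1:
            raise ValueError("gap_closing_max_frame_gap must be >= 1")
        if self.alternative_cost_factor <= 1:
            raise ValueError("alternative_cost_factor must be > 1")


@dataclass
class TrackFilter:
    """Post-hoc track selection.

    ``min_duration`` (frames) and ``min_quality`` (mean spot quality) each
    accept a number, ``"auto"`` (Otsu's threshold on the per-track feature
    distribution, keeping the upper mode), or None (no filtering).
    """

    min_duration: float | str | None = None
    min_quality: float | str | None = None

    def __post_init__(self) -> None:
        for name in ("min_duration", "min_quality"):
            v = getattr(self, name)
            if v is None or v == "auto":
                continue
            if not (float(v) >= 0):
                raise ValueError(f"{name} must be >= 0 or 'auto', got {v!r}")


@dataclass
class AssignmentResult:
    """Solution of one augmented assignment problem."""

    links: list[tuple[int, int]]  # (source, target) pairs actually linked
    total_cost: float  # link costs + alternative cost per unlinked item
    alternative_cost: float


def solve_assignment(
    cost: np.ndarray,
    alternative_cost: float | None = None,
    alternative_cost_factor: float = 1.05,
    augment: bool = True,
) -> AssignmentResult:
    """Optimally assign sources to targets with birth/death alternatives.

    ``cost`` is an (n, m) matrix; forbidden entries are ``inf``.  The
    matrix is augmented to (n+m) x (n+m): every source may go unmatched
    ("death") and every target may appear unmatched ("birth"), each at
    ``alternative_cost`` (default: ``alternative_cost_factor`` times the
    maximum finite entry).  The returned links minimize

        sum(linked costs) + b * (#unlinked sources + #unlinked targets)

    globally — this is an exact optimum, not a greedy matching.  With
    ``augment=False`` a plain square assignment is solved and an infeasible
    matrix raises.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2D matrix")
    n, m = cost.shape
    finite = np.isfinite(cost)

    if not augment:
        if not finite.all() or n != m:
            raise ValueError(
                "without augmentation the cost matrix must be square and "
                "fully feasible"
            )
        rows, cols = linear_sum_assignment(cost)
        total = float(cost[rows, cols].sum())
        return AssignmentResult(list(zip(rows, cols)), total, np.nan)

    if not finite.any():
        b = 0.0 if alternative_cost is None else float(alternative_cost)
        return AssignmentResult([], b * (n + m), b)

    if alternative_cost is None:
        b = alternative_cost_factor * float(cost[finite].max())
    else:
        b = float(alternative_cost)

    # Augmented square matrix; the forbidden sentinel exceeds birth+death so
    # a forbidden link can never beat the unlinked alternative.
    sentinel = 2.0 * abs(b) + float(cost[finite].max()) + 1.0
    aug = np.full((n + m, n + m), sentinel)
    aug[:n, :m] = np.where(finite, cost, sentinel)
    aug[:n, m:] = sentinel
    aug[np.arange(n), m + np.arange(n)] = b  # deaths
    aug[n:, :m] = sentinel
    aug[n + np.arange(m), np.arange(m)] = b  # births
    aug[n:, m:] = 0.0  # dummy-dummy completions are free

    rows, cols = linear_sum_assignment(aug)
    links = [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and finite[r, c]
    ]
    total = float(sum(cost[r, c] for r, c in links)) + b * (
        (n - len(links)) + (m - len(links))
    )
    return AssignmentResult(links, total, b)


def _pair_costs(
    sources: list[Spot], targets: list[Spot], max_distance: float
) -> np.ndarray:
    a = np.array([[s.x, s.y] for s in sources])
    b = np.array([[s.x, s.y] for s in targets])
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    d2[d2 > max_distance**2] = np.inf
    return d2


def link_frames(spots: list[Spot], params: LinkingParams) -> list[list[Spot]]:
    """Frame-to-frame linking; returns track segments (lists of spots).

    Segments may be single spots; ``close_gaps`` later discards those that
    never join anything (a valid track needs at least two detections).
    """
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    if not by_frame:
        return []
    frames = sorted(by_frame)

    segments: list[list[Spot]] = [[s] for s in by_frame[frames[0]]]
    for t in frames:
        if t + 1 not in by_frame:
            continue
        sources = [seg for seg in segments if seg[-1].frame == t]
        targets = by_frame[t + 1]
        if sources:
            cost = _pair_costs(
                [seg[-1] for seg in sources], targets, params.linking_max_distance
            )
            res = solve_assignment(
                cost, alternative_cost_factor=params.alternative_cost_factor
            )
            linked_targets = set()
            for i, j in res.links:
                sources[i].append(targets[j])
                linked_targets.add(j)
        else:
            linked_targets = set()
        segments.extend(
            [targets[j]] for j in range(len(targets)) if j not in linked_targets
        )
    return segments


def close_gaps(segments: list[list[Spot]], params: LinkingParams) -> list[Track]:
    """Join segment ends to later segment starts across detection gaps.

    Feasible pairs satisfy ``1 <= frame(start) - frame(end) <=
    gap_closing_max_frame_gap`` and ``distance <=
    gap_closing_max_distance``; the assignment minimizing total squared
    distance (with birth/death alternatives) decides the joins.  Joined
    chains concatenate into final tracks; segments of fewer than two spots
    that join nothing are dropped.
    """
    n = len(segments)
    if n == 0:
        return []
    cost = np.full((n, n), np.inf)
    for i, seg_i in enumerate(segments):
        end = seg_i[-1]
        for j, seg_j in enumerate(segments):
            if i == j:
                continue
            start = seg_j[0]
            gap = start.frame - end.frame
            if not (1 <= gap <= params.gap_closing_max_frame_gap):
                continue
            d2 = (end.x - start.x) ** 2 + (end.y - start.y) ** 2
            if d2 <= params.gap_closing_max_distance**2:
                cost[i, j] = d2
    res = solve_assignment(
        cost, alternative_cost_factor=params.alternative_cost_factor
    )
    successor = dict(res.links)
    has_predecessor = set(successor.values())

    tracks: list[Track] = []
    tid = 0
    for i in range(n):
        if i in has_predecessor:
            continue
        chain = list(segments[i])
        j = i
        while j in successor:
            j = successor[j]
            chain.extend(segments[j])
        if len(chain) >= 2:
            tracks.append(Track(track_id=tid, spots=chain))
            tid += 1
    return tracks


def _otsu_threshold(values: np.ndarray) -> float:
    if values.size < 2 or np.ptp(values) == 0:
        return float(values.min()) if values.size else 0.0
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values.astype(np.float64)))


def filter_tracks(tracks: list[Track], track_filter: TrackFilter) -> list[Track]:
    """Keep tracks whose duration and mean quality clear their thresholds.

    ``"auto"`` thresholds come from Otsu's method on the per-track feature
    distribution; tracks at or above the threshold survive.
    """
    if not tracks:
        return []
    kept = list(tracks)
    if track_filter.min_duration is not None:
        durations = np.array([t.duration_frames for t in kept], dtype=float)
        thr = (
            _otsu_threshold(durations)
            if track_filter.min_duration == "auto"
            else float(track_filter.min_duration)
        )
        kept = [t for t, d in zip(kept, durations) if d >= thr]
    if track_filter.min_quality is not None and kept:
        quals = np.array([t.mean_quality() for t in kept])
        thr = (
            _otsu_threshold(quals)
            if track_filter.min_quality == "auto"
            else float(track_filter.min_quality)
        )
        kept = [t for t, q in zip(kept, quals) if q >= thr]
    return kept


def subsample_tracks(tracks: list[Track], n: int, seed: int) -> list[Track]:
    """Uniform random sample of min(n, total) tracks without replacement.

    Deterministic for a given seed; the original order is preserved within
    the sample.  Useful when a downstream plot can only hold a limited
    number of series (e.g. 256 trajectories).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n >= len(tracks):
        return list(tracks)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(tracks), size=n, replace=False))
    return [tracks[i] for i in idx]
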