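"""Synthetic time-lapse videos of migrating cells with known ground truth.

The generator emulates a phase-contrast 3D chemotaxis assay after
background subtraction: bright, blob-like cells (diameter ~30-40 um) move
through the field as persistent random walkers, optionally biased along +x
— the direction standing in for the chemoattractant gradient.  Defaults
describe a dendritic-cell-like acquisition: 2 um pixels, 2 min frame
interval, 30 um blobs, ~5 um/min speeds, and a peak signal-to-noise ratio
of 5.

Motion model, per cell and per frame:

    theta_{t+1} = theta_t + eps,        eps ~ Normal(0, persistence_sd)
    u_t = normalize((1 - b) * (cos theta_t, sin theta_t) + b * (1, 0))
    step_t = max(0, Normal(speed_mean, speed_sd)) * frame_interval * u_t

with ``b = bias_weight`` in [0, 1] (0: unbiased persistent random walk,
1: fully directed).  Positions reflect at the field boundary so all tracks
keep a full complement of frames.  ``vanish_probability`` hides a cell from
individual rendered frames to create detection gaps for gap-closing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .stackio import (
    CalibrationMetadata,
    ImageStack,
    Spot,
    Track,
    write_stack,
    write_spots_table,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tracks",
    "render_video",
    "make_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic migration video.

    Defaults match a dendritic-cell-like acquisition on a processed
    (background-subtracted) video: 256 x 256 px at 2 um/px, 50 frames at
    2 min, 20 cells of 30 um diameter, blob amplitude 100 over Gaussian
    noise of SD 20 (peak SNR 5).
    """

    n_cells: int = 20
    image_size: tuple[int, int] = (256, 256)  # (H, W) px
    calibration: CalibrationMetadata = field(
        default_factory=lambda: CalibrationMetadata(pixel_size=2.0, frame_interval=2.0)
    )
    speed_mean: float = 5.0  # um/min
    speed_sd: float = 1.0  # um/min
    persistence_sd: float = 0.4  # radians per step
    bias_weight: float = 0.0  # 0 = random, 1 = fully directed along +x
    blob_diameter: float = 30.0  # um
    blob_amplitude: float = 100.0  # intensity units
    background_texture_amplitude: float = 0.0  # intensity units
    noise_sd: float = 20.0  # intensity units
    n_frames: int = 50
    vanish_probability: float = 0.0
    min_separation: float | None = None  # um; None = one blob diameter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias_weight <= 1.0):
            raise ValueError(f"bias_weight must be in [0, 1], got {self.bias_weight}")
        if not (self.speed_mean > 0):
            raise ValueError(f"speed_mean must be > 0, got {self.speed_mean}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not (0.0 <= self.vanish_probability < 1.0):
            raise ValueError(
                f"vanish_probability must be in [0, 1), got {self.vanish_probability}"
            )
        if isinstance(self.calibration, dict):
            self.calibration = CalibrationMetadata(**self.calibration)
        self.image_size = tuple(int(v) for v in self.image_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """True trajectories (um) and the per-(cell, frame) rendering mask."""

    tracks: list[Track]
    rendered_mask: np.ndarray  # (n_cells, n_frames) bool

    def __post_init__(self) -> None:
        self.rendered_mask = np.asarray(self.rendered_mask, dtype=bool)
        n_frames = len(self.tracks[0].spots)
        for tr in self.tracks:
            if len(tr.spots) != n_frames:
                raise ValueError("all true tracks must span every frame")
        if self.rendered_mask.shape != (len(self.tracks), n_frames):
            raise ValueError("rendered_mask shape must be (n_cells, n_frames)")


def _reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return v + lo


def simulate_tracks(config: SimulationConfig) -> GroundTruth:
    """Simulate biased persistent random walks for every cell.

    All randomness comes from a generator seeded with ``config.seed``;
    identical configs give identical ground truth.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    p = config.calibration.pixel_size
    dt = config.calibration.frame_interval
    x_max, y_max = (w - 1) * p, (h - 1) * p
    # Trajectories reflect at a blob-radius inset so cells never leave the
    # resolvable field; initial positions start further inside.
    wall = min(config.blob_diameter / 2.0, 0.2 * min(x_max, y_max))
    margin = min(config.blob_diameter, 0.4 * min(x_max, y_max))

    b = config.bias_weight
    # Cells exclude volume: centres stay at least one blob diameter apart
    # (cells in a gel cannot interpenetrate), so blobs never coalesce.
    min_sep = (
        config.blob_diameter if config.min_separation is None else config.min_separation
    )

    # Initial positions: uniform in the interior, rejection-sampled to
    # respect the separation constraint where the field allows it.
    positions = np.empty((config.n_cells, 2))
    for cid in range(config.n_cells):
        for _ in range(200):
            cand = np.array(
                [rng.uniform(margin, x_max - margin), rng.uniform(margin, y_max - margin)]
            )
            if cid == 0 or np.hypot(
                *(positions[:cid] - cand).T
            ).min() >= min_sep:
                break
        positions[cid] = cand

    thetas = rng.uniform(-np.pi, np.pi, size=config.n_cells)
    traj = np.empty((config.n_cells, config.n_frames, 2))
    traj[:, 0] = positions
    for t in range(1, config.n_frames):
        for cid in range(config.n_cells):
            theta = np.mod(
                thetas[cid] + rng.normal(0.0, config.persistence_sd) + np.pi,
                2 * np.pi,
            ) - np.pi
            step = max(0.0, rng.normal(config.speed_mean, config.speed_sd)) * dt
            x, y = positions[cid]
            for attempt in range(9):
                ux = (1 - b) * np.cos(theta) + b
                uy = (1 - b) * np.sin(theta)
                norm = np.hypot(ux, uy)
                if norm < 1e-12:
                    ux, uy, norm = 1.0, 0.0, 1.0
                nx = _reflect(x + step * ux / norm, wall, x_max - wall)
                ny = _reflect(y + step * uy / norm, wall, y_max - wall)
                others = np.delete(positions, cid, axis=0)
                if config.n_cells == 1 or np.hypot(
                    *(others - (nx, ny)).T
                ).min() >= min_sep:
                    break
                # Blocked by a neighbour: try a fresh heading.
                theta = rng.uniform(-np.pi, np.pi)
            else:
                nx, ny = x, y  # fully surrounded (rare): stall this frame
            thetas[cid] = theta
            positions[cid] = (nx, ny)
        traj[:, t] = positions

    tracks = [
        Track(
            track_id=cid,
            spots=[
                Spot(frame=t, x=float(traj[cid, t, 0]), y=float(traj[cid, t, 1]), quality=1.0)
                for t in range(config.n_frames)
            ],
        )
        for cid in range(config.n_cells)
    ]

    mask = rng.random((config.n_cells, config.n_frames)) >= config.vanish_probability
    return GroundTruth(tracks=tracks, rendered_mask=mask)


def render_video(truth: GroundTruth, config: SimulationConfig) -> ImageStack:
    """Render ground-truth tracks into an intensity stack.

    Each frame is the sum of a static collagen-like background texture
    (seeded smoothed noise, identical in every frame), one isotropic
    Gaussian bump of SD ``blob_diameter / 4`` per rendered cell, and
    independent per-pixel Gaussian noise; intensities are clipped at 0.
    """
    p = config.calibration.pixel_size
    if config.blob_diameter < 2 * p:
        raise ValueError(
            f"blob_diameter {config.blob_diameter} um is below 2 px "
            f"({2 * p} um): unresolvable"
        )
    h, w = config.image_size
    # Separate stream so rendering noise never perturbs the trajectories.
    rng = np.random.default_rng([config.seed, 0xB10B])

    if config.background_texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((h, w)), sigma=4.0)
        tex *= config.background_texture_amplitude / tex.std()
        tex -= tex.min()  # texture is an additive non-negative background
    else:
        tex = np.zeros((h, w))

    sigma_px = (config.blob_diameter / 4.0) / p
    rad = int(np.ceil(4 * sigma_px))
    frames = np.empty((config.n_frames, h, w))
    for t in range(config.n_frames):
        img = tex.copy()
        for cid, tr in enumerate(truth.tracks):
            if not truth.rendered_mask[cid, t]:
                continue
            s = tr.spots[t]
            c, r = s.x / p, s.y / p
            r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
            c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            img[r0:r1, c0:c1] += config.blob_amplitude * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_px**2)
            )
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[t] = np.clip(img, 0.0, None)

    return ImageStack(frames=frames, calibration=config.calibration)


def make_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic fixture: TIFF stack, ground-truth CSV
    (concatenated layout) and the YAML config.

    Regeneration with the same seed is byte-identical for the CSV and
    value-identical for the TIFF.
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        out_dir.mkdir(parents=True)
    truth = simulate_tracks(config)
    stack = render_video(truth, config)
    paths = {
        "stack": write_stack(stack, out_dir / "stack.tif"),
        "ground_truth": write_spots_table(
            truth.tracks, out_dir / "ground_truth.csv", layout="diper"
        ),
        "config": out_dir / "config.yaml",
    }
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
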