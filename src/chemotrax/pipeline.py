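"""End-to-end pipeline: preprocess -> detect -> link -> filter -> summarize.

All stage parameters live in a single :class:`PipelineConfig`, loadable
from YAML, so a run is fully described by one file plus the input stack;
re-running with identical config and inputs is value-identical because
every source of randomness is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .stackio import (
    CalibrationMetadata,
    ImageStack,
    Track,
    read_stack,
    write_stack,
    write_spots_table,
    render_overlay,
)
from .preprocess import PreprocessParams, preprocess_stack
from .detect import DetectionParams, detect_spots
from .track import (
    LinkingParams,
    TrackFilter,
    link_frames,
    close_gaps,
    filter_tracks,
    subsample_tracks,
)
from .motility import MotilitySummary, summarize, plot_at_origin, compare_conditions
from .simulate import SimulationConfig, make_fixture

__all__ = ["PipelineConfig", "run_pipeline", "run_simulation", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Every parameter of a tracking run, in one validated object.

    Defaults encode the dendritic-cell acquisition profile: 30 um blobs,
    quality threshold 25, 50 um linking and gap-closing radii, frame gap 8,
    0.1 % contrast saturation.
    """

    calibration: CalibrationMetadata = field(
        default_factory=lambda: CalibrationMetadata(pixel_size=2.0, frame_interval=2.0)
    )
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    track_filter: TrackFilter = field(default_factory=TrackFilter)
    subsample_n: int | None = None
    subsample_seed: int = 0
    condition_label: str = ""
    skip_preprocess: bool = False

    _SECTIONS = {
        "calibration": CalibrationMetadata,
        "preprocess": PreprocessParams,
        "detection": DetectionParams,
        "linking": LinkingParams,
        "track_filter": TrackFilter,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for name, typ in cls._SECTIONS.items():
            if name in d:
                section = d.pop(name)
                if not isinstance(section, dict):
                    raise ValueError(f"{name}: expected a mapping")
                try:
                    kwargs[name] = typ(**section)
                except TypeError as e:
                    raise ValueError(f"{name}: {e}") from e
        known = {"subsample_n", "subsample_seed", "condition_label", "skip_preprocess"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline fields: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def run_pipeline(
    config: PipelineConfig,
    input_stack: str | Path | ImageStack,
    out_dir: str | Path,
) -> dict:
    """Run the complete workflow on one stack and write the result bundle.

    Outputs: processed stack, spots table, tracks table (both layouts),
    overlay video, per-track and MSD CSVs, origin-aligned trajectory plot,
    and a machine-readable run log with every parameter and per-stage
    count.  Returns a dict with the tracks, the summary and the log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrap

    if isinstance(input_stack, ImageStack):
        stack = input_stack
    else:
        stack = stage("read")(read_stack, input_stack, config.calibration)
    log["stages"]["read"] = {"n_frames": stack.n_frames, "shape": list(stack.shape)}

    if config.skip_preprocess:
        processed = stack
    else:
        processed = stage("preprocess")(preprocess_stack, stack, config.preprocess)
        write_stack(processed, out_dir / "processed.tif")

    spots = stage("detect")(detect_spots, processed, config.detection)
    log["stages"]["detect"] = {"n_spots": len(spots)}

    segments = stage("link")(link_frames, spots, config.linking)
    log["stages"]["link"] = {"n_segments": len(segments)}
    tracks = stage("gap_closing")(close_gaps, segments, config.linking)
    log["stages"]["gap_closing"] = {"n_tracks": len(tracks)}

    tracks = stage("filter")(filter_tracks, tracks, config.track_filter)
    log["stages"]["filter"] = {"n_tracks": len(tracks)}
    if config.subsample_n is not None and tracks:
        tracks = subsample_tracks(tracks, config.subsample_n, config.subsample_seed)
        log["stages"]["subsample"] = {
            "n_tracks": len(tracks),
            "seed": config.subsample_seed,
        }

    summary = None
    if tracks:
        write_spots_table(tracks, out_dir / "tracks.csv", layout="spots_in_tracks")
        write_spots_table(tracks, out_dir / "tracks_diper.csv", layout="diper")
        stage("overlay")(render_overlay, processed, tracks, out_dir / "overlay.tif")
        summary = stage("stats")(
            summarize, tracks, config.calibration, config.condition_label, out_dir
        )
        plot_tracks = (
            subsample_tracks(tracks, 256, config.subsample_seed)
            if len(tracks) > 256
            else tracks
        )
        stage("plot")(plot_at_origin, plot_tracks, out_dir / "tracks_at_origin.png")

    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)
    return {"tracks": tracks, "summary": summary, "log": log}


def run_simulation(config_path: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic fixture from a YAML simulation config."""
    with open(config_path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        config = SimulationConfig.from_dict(data)
    except TypeError as e:
        raise ValueError(str(e)) from e
    return make_fixture(config, out_dir)


def compare_summaries(
    a: MotilitySummary, b: MotilitySummary, features: tuple[str, ...] = ("speed", "directionality")
) -> dict:
    """Mann-Whitney comparison of two conditions on the given features."""
    report = {}
    for feat in features:
        r = compare_conditions(a, b, feat)
        report[feat] = {
            "u_statistic": r.u_statistic,
            "p_value": r.p_value,
            "method": r.method,
            a.condition_label or "a": {"mean": r.mean_a, "sem": r.sem_a, "n": r.n_a},
            b.condition_label or "b": {"mean": r.mean_b, "sem": r.sem_b, "n": r.n_b},
        }
    return report
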