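"""Stack I/O, pipeline configuration, and the end-to-end pipeline.

Stacks are written as multi-page TIFF with the axis order (t, c, z, y, x)
and the physical calibration (voxel sizes in um, frame interval in s)
stored in the TIFF's JSON shape metadata, and read back with the
calibration attached. Files lacking calibration are rejected rather than
silently assigned defaults.

``run_pipeline`` chains simulate -> detect -> track -> trace -> summarize
-> timeline on a single configuration object whose seed is the only source
of randomness; rerunning the same config reproduces the same tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import detect as _detect
from . import simulate as _sim
from . import traces as _traces
from .timeline import PairwiseDelay, assemble_timeline

__all__ = ["StackMeta", "PipelineConfig", "read_stack", "write_stack", "run_pipeline"]

log = logging.getLogger("cistrack")


@dataclass(frozen=True)
class StackMeta:
    voxel_z: float
    voxel_xy: float
    frame_interval: float

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return (self.voxel_z, self.voxel_xy, self.voxel_xy)


def write_stack(path: str | Path, stack: np.ndarray, meta: StackMeta) -> None:
    """Write a (t, c, z, y, x) stack as TIFF with embedded calibration."""
    stack = np.asarray(stack)
    if stack.ndim != 5:
        raise ValueError(f"expected a 5D t,c,z,y,x stack, got shape {stack.shape}")
    tifffile.imwrite(
        str(path),
        stack,
        metadata={
            "axes": "TCZYX",
            "voxel_z_um": meta.voxel_z,
            "voxel_xy_um": meta.voxel_xy,
            "frame_interval_s": meta.frame_interval,
        },
    )


def read_stack(
    path: str | Path,
    voxel_z: float | None = None,
    voxel_xy: float | None = None,
    frame_interval: float | None = None,
) -> tuple[np.ndarray, StackMeta]:
    """Read a calibrated stack; calibration must be embedded or supplied.

    2D/3D/4D TIFFs are promoted to 5D by prepending singleton t/c/z axes
    only when the embedded axes string says so; an ambiguous file without
    an axes declaration is an error.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        shaped = tif.shaped_metadata
        meta_dict = dict(shaped[0]) if shaped else {}
    axes = meta_dict.get("axes")
    if axes is None:
        raise ValueError(
            f"{path}: no axes metadata; write stacks with cistrack.io.write_stack "
            "or declare axes explicitly"
        )
    axes = axes.upper()
    if set(axes) - set("TCZYX") or axes[-2:] != "YX":
        raise ValueError(f"{path}: unsupported axes {axes!r}")
    for ax in "TCZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    data = np.moveaxis(data, [axes.index(a) for a in "TCZYX"], range(5))

    vz = voxel_z if voxel_z is not None else meta_dict.get("voxel_z_um")
    vxy = voxel_xy if voxel_xy is not None else meta_dict.get("voxel_xy_um")
    dt = frame_interval if frame_interval is not None else meta_dict.get("frame_interval_s")
    if vz is None or vxy is None or dt is None:
        raise ValueError(
            f"{path}: missing calibration (voxel sizes / frame interval); "
            "pass them explicitly"
        )
    return data, StackMeta(voxel_z=float(vz), voxel_xy=float(vxy), frame_interval=float(dt))


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end maturation pipeline, with defaults.

    ``mean_delta_s`` / ``sd_delta_s`` / ``n_cisternae`` parameterize the
    simulated experiment (per-cisterna red-minus-green peak delays); the
    remaining fields control detection, tracking and trace analysis.
    """

    mean_delta_s: float = 31.0
    sd_delta_s: float = 24.1
    n_cisternae: int = 10
    seed: int = 1
    pair_label: str = "green->red"
    # detection
    min_diameter_um: float = 0.25
    max_diameter_um: float = 0.9
    threshold_sd: float = 5.0
    # tracking
    max_displacement_um: float = 0.5
    max_gap_frames: int = 2
    # traces
    roi_radius_um: float = 0.35
    background: str = "none"
    smoothing_window: int = 3
    min_track_frames: int = 5

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate, analyze, and write the full results bundle.

    Outputs in ``out_dir``: movie.tif, truth.* (ground truth), tracks.csv,
    traces.csv, summary.csv, timeline.csv, pipeline.log, config.json. The
    returned dict carries the in-memory results. All CSVs are stamped with
    the config hash and seed via config.json alongside them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    config.to_json(out / "config.json")
    log.info("config hash=%s seed=%d", config.config_hash(), config.seed)

    acq, scene = _sim.maturation_scene(
        config.mean_delta_s, config.sd_delta_s, config.n_cisternae, seed=config.seed
    )
    stack, truth = _sim.generate_movie(acq, scene)
    meta = StackMeta(acq.voxel_z, acq.voxel_xy, acq.frame_interval)
    write_stack(out / "movie.tif", stack, meta)
    truth.save(out / "truth")
    log.info("simulate: %d cisternae, %d frames", len(scene), acq.n_frames)

    if config.n_cisternae == 0 or not scene:
        log.warning("empty scene: writing empty tables")

    spots = _detect.detect_spots_movie(
        stack,
        meta.voxel_size,
        min_diameter=config.min_diameter_um,
        max_diameter=config.max_diameter_um,
        threshold=config.threshold_sd,
        psf_sigma_xy=acq.psf_sigma_xy,
        psf_sigma_z=acq.psf_sigma_z,
    )
    log.info("detect: %d spots", len(spots))
    tracks = _detect.link_tracks(
        spots, config.max_displacement_um, config.max_gap_frames
    )
    _detect.tracks_table(tracks).to_csv(out / "tracks.csv", index=False)
    log.info("track: %d tracks", len(tracks))

    summary, traces, pairs, reasons = _traces.summarize_maturation(
        tracks,
        stack,
        meta.voxel_size,
        meta.frame_interval,
        roi_radius_um=config.roi_radius_um,
        background=config.background,
        smoothing_window=config.smoothing_window,
        min_track_frames=config.min_track_frames,
        label=config.pair_label,
    )
    for line in reasons:
        log.info("trace: %s", line)
    log.info(
        "summarize: n=%d mean_delta=%.2f s sd=%.2f s",
        summary.n,
        summary.mean_delta_s,
        summary.sd_delta_s,
    )

    trace_rows = []
    for tr in traces:
        norm = tr.normalized
        for c in range(tr.n_channels):
            for t, f_raw, f_n in zip(tr.times, tr.intensity[:, c], norm[:, c]):
                trace_rows.append(
                    {
                        "track_id": tr.track_id,
                        "channel": c,
                        "time_s": t,
                        "F": f_raw,
                        "F_norm": f_n,
                    }
                )
    pd.DataFrame(trace_rows, columns=["track_id", "channel", "time_s", "F", "F_norm"]).to_csv(
        out / "traces.csv", index=False
    )
    summary.to_frame().to_csv(out / "summary.csv", index=False)

    green, red = (config.pair_label.split("->") + ["green", "red"])[:2]
    tl = assemble_timeline(
        [PairwiseDelay(green, red, summary.mean_delta_s, summary.sd_delta_s, summary.n)],
        anchor=green,
    )
    pd.DataFrame(
        {"marker": list(tl.times), "peak_time_s": list(tl.times.values())}
    ).to_csv(out / "timeline.csv", index=False)

    return {
        "config": config,
        "acquisition": acq,
        "truth": truth,
        "tracks": tracks,
        "traces": traces,
        "pairs": pairs,
        "summary": summary,
        "timeline": tl,
    }
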