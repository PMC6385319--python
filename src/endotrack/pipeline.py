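"""End-to-end orchestration of the motility pipeline.

One :class:`PipelineConfig` carries every stage parameter; the pipeline
runs simulate (optional) -> restore -> detect -> link -> motility ->
speed-mixture, and FLIM fitting on gated stacks, writing CSV/JSON/PNG
outputs stamped with the config hash.  Identical config + seed gives an
identical result bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as etio
from .detect import SpotDetector
from .link import TrackLinker
from .mixture import fit_mixture
from .motility import direction_stats, extract_all_segments, segments_to_frame
from .restore import BFBDFilter
from .simulate import MotionModel, SimulationConfig, render_movie, simulate_tracks

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    # stage toggles
    simulate: bool = True
    restore: bool = True
    detect: bool = True
    link: bool = True
    motility: bool = True
    mixture: bool = True
    kymograph: bool = True
    # calibration / geometry
    pixel_size_um: float = 0.167
    frame_interval_s: float = 0.33
    soma_side: str = "left"
    seed: int = 0
    # simulate
    sim_n_frames: int = 120
    sim_n_endosomes: int = 12
    sim_axon_length_px: int = 256
    sim_image_height_px: int = 32
    sim_intensity_mu: float = 450.0
    sim_intensity_sigma: float = 0.3
    sim_coupling: float = 0.0
    # restore
    temporal_window: int = 19
    background_model: str = "constant"
    bilinear: bool = False
    # detect
    alpha: float = 0.01
    spot_w0: float = 2.0
    # link
    max_speed_um_s: float = 10.0
    max_gap: int = 1
    # motility
    min_run: int = 4
    # mixture
    fit_range: tuple[float, float] = (0.07, 10.0)
    n_bins: int = 40
    k_max: int = 3
    # output
    out_dir: str = "endotrack_out"

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_json(self, path) -> None:
        etio.write_json(path, dataclasses.asdict(self))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = etio.read_json(path)
        if "fit_range" in data:
            data["fit_range"] = tuple(data["fit_range"])
        return cls(**data)


def _kymograph_png(path, movie: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kymo = movie.max(axis=1)  # x-t projection along the axon axis
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(kymo, aspect="auto", cmap="gray", origin="upper")
    ax.set_xlabel("position along axon (px)")
    ax.set_ylabel("time (frame)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, movie: np.ndarray | None = None) -> dict:
    """Execute the configured stages; returns a result bundle dict.

    ``movie`` may be supplied instead of the synthetic-simulation stage.
    Raises with the stage name on stage failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.hash()
    config.to_json(out / f"config_{tag}.json")
    bundle: dict = {"config_hash": tag}

    stage = "simulate"
    try:
        if config.simulate and movie is None:
            sim = SimulationConfig(
                axon_length_px=config.sim_axon_length_px,
                image_height_px=config.sim_image_height_px,
                pixel_size_um=config.pixel_size_um,
                frame_interval_s=config.frame_interval_s,
                n_frames=config.sim_n_frames,
                n_endosomes=config.sim_n_endosomes,
                intensity_mu=config.sim_intensity_mu,
                intensity_sigma=config.sim_intensity_sigma,
                intensity_motility_coupling=config.sim_coupling,
                soma_side=config.soma_side,
                seed=config.seed,
            )
            truth = simulate_tracks(MotionModel(), sim)
            movie = render_movie(truth, sim)
            etio.write_movie_tiff(out / f"movie_{tag}.tif", movie)
            etio.write_tracks_csv(out / f"truth_{tag}.csv", truth.tracks)
            bundle["truth"] = truth
        if movie is None:
            raise ValueError("no input movie and simulation disabled")
        bundle["movie"] = movie

        stage = "restore"
        restored = None
        if config.restore:
            restored = BFBDFilter(
                temporal_window=config.temporal_window,
                model=config.background_model,
                bilinear=config.bilinear,
            ).transform(movie)
            bundle["restored"] = restored

        stage = "detect"
        detections = None
        if config.detect:
            if restored is None:
                raise ValueError("detect requires the restore stage")
            detections = SpotDetector(alpha=config.alpha, w0=config.spot_w0).detect_movie(
                restored
            )
            etio.write_tracks_csv(out / f"detections_{tag}.csv", detections)
            bundle["detections"] = detections

        stage = "link"
        tracks = None
        if config.link and detections is not None:
            tracks = TrackLinker(
                max_speed_um_s=config.max_speed_um_s,
                max_gap=config.max_gap,
                pixel_size_um=config.pixel_size_um,
                frame_interval_s=config.frame_interval_s,
            ).fit(detections).tracks_
            etio.write_tracks_csv(out / f"tracks_{tag}.csv", tracks)
            bundle["tracks"] = tracks

        stage = "motility"
        segments = None
        if config.motility and tracks is not None:
            segments = extract_all_segments(
                tracks,
                config.pixel_size_um,
                config.frame_interval_s,
                soma_side=config.soma_side,
                min_run=config.min_run,
            )
            seg_df = segments_to_frame(segments)
            etio.write_tracks_csv(out / f"segments_{tag}.csv", seg_df)
            stats = direction_stats(segments)
            etio.write_json(
                out / f"direction_stats_{tag}.json",
                {k: dataclasses.asdict(v) for k, v in stats.items()},
            )
            bundle["segments"] = segments
            bundle["direction_stats"] = stats

        stage = "mixture"
        if config.mixture and segments is not None:
            fits = {}
            for direction in ("retrograde", "anterograde"):
                speeds = np.concatenate(
                    [s.step_speeds for s in segments if s.direction == direction]
                    or [np.array([])]
                )
                in_range = speeds[
                    (speeds >= config.fit_range[0]) & (speeds <= config.fit_range[1])
                ]
                if in_range.size >= 50:
                    fits[direction] = fit_mixture(
                        speeds,
                        k_max=config.k_max,
                        fit_range=config.fit_range,
                        n_bins=config.n_bins,
                    )
            etio.write_json(
                out / f"mixture_{tag}.json",
                {k: dataclasses.asdict(v) for k, v in fits.items()},
            )
            bundle["mixture"] = fits

        stage = "kymograph"
        if config.kymograph:
            _kymograph_png(out / f"kymograph_{tag}.png", movie)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
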