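"""Track-level motility observables.

Converts linked endosome tracks into the observables of axonal-transport
quantification: processive (unidirectional) runs of at least ``min_run``
consecutive frames, their direction relative to the soma, displacements,
per-step speeds, movement-event counts, and per-direction fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProcessiveSegment",
    "DirectionStats",
    "extract_segments",
    "extract_all_segments",
    "segments_to_frame",
    "direction_stats",
    "compare_groups",
]

RETROGRADE = "retrograde"
ANTEROGRADE = "anterograde"


@dataclass
class ProcessiveSegment:
    """A maximal unidirectional run of >= min_run consecutive frames.

    ``displacement_um`` is the summed absolute axial step length of the run
    (the distance of non-stop unidirectional movement); ``step_speeds`` are
    the per-step speeds in µm/s; direction is retrograde when the steps
    point toward the soma.
    """

    track_id: int
    direction: str
    start_frame: int
    n_frames: int
    displacement_um: float
    step_speeds: np.ndarray
    mean_speed: float
    mean_intensity: float


@dataclass
class DirectionStats:
    """Per-direction summary of processive segments."""

    direction: str
    n_segments: int
    n_movement_events: int
    mean_displacement_um: float
    sem_displacement_um: float
    mean_speed_um_s: float
    sem_speed_um_s: float
    flux: float  # mean speed x number of movement events


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0 if x.size == 1 else float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def extract_segments(
    frames,
    x_px,
    pixel_size_um: float,
    frame_interval_s: float,
    soma_side: str = "left",
    min_run: int = 4,
    min_step_um: float | None = None,
    intensity=None,
    track_id: int = 0,
) -> list[ProcessiveSegment]:
    """Extract maximal processive runs from one track.

    A processive run is a stretch of at least ``min_run`` consecutive
    frames over which every axial step has the same sign and magnitude at
    least ``min_step_um`` (default half a pixel, a dead band against
    localisation jitter).  Direction is measured along the axon axis only:
    retrograde means steps toward the soma side.

    Parameters
    ----------
    frames, x_px : array-like
        Frame indices (consecutive integers within a run) and axial
        positions in pixels, time-ordered.
    soma_side : {"left", "right"}
        Side of the image the cell body is on; with the soma on the left,
        retrograde movement has decreasing x.
    """
    if soma_side not in ("left", "right"):
        raise ValueError(f"undefined axon axis: soma_side={soma_side!r}")
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("pixel_size_um and frame_interval_s must be positive")
    frames = np.asarray(frames, dtype=int)
    x_um = np.asarray(x_px, dtype=float) * pixel_size_um
    if min_step_um is None:
        min_step_um = 0.5 * pixel_size_um
    if intensity is None:
        intensity = np.full(len(frames), np.nan)
    intensity = np.asarray(intensity, dtype=float)

    n = len(frames)
    if n < min_run:
        return []
    dx = np.diff(x_um)
    consec = np.diff(frames) == 1
    valid = (np.abs(dx) >= min_step_um) & consec
    sign = np.sign(dx)

    segments: list[ProcessiveSegment] = []
    i = 0
    while i < n - 1:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n - 1 and valid[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        n_steps = j - i + 1
        if n_steps >= min_run - 1:
            steps = dx[i : j + 1]
            speeds = np.abs(steps) / frame_interval_s
            toward_soma = (sign[i] < 0) == (soma_side == "left")
            window_int = intensity[i : j + 2]
            finite = window_int[np.isfinite(window_int)]
            mean_int = float(finite.mean()) if finite.size else float("nan")
            segments.append(
                ProcessiveSegment(
                    track_id=int(track_id),
                    direction=RETROGRADE if toward_soma else ANTEROGRADE,
                    start_frame=int(frames[i]),
                    n_frames=n_steps + 1,
                    displacement_um=float(np.abs(steps).sum()),
                    step_speeds=speeds,
                    mean_speed=float(speeds.mean()),
                    mean_intensity=mean_int,
                )
            )
        i = j + 1
    return segments


def extract_all_segments(
    tracks: pd.DataFrame,
    pixel_size_um: float,
    frame_interval_s: float,
    soma_side: str = "left",
    min_run: int = 4,
    min_step_um: float | None = None,
) -> list[ProcessiveSegment]:
    """Run :func:`extract_segments` over every track of a track table.

    ``tracks`` needs columns ``track_id``, ``frame``, ``x``; optional
    ``integral_intensity``.
    """
    segments: list[ProcessiveSegment] = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        inten = (
            grp["integral_intensity"].to_numpy()
            if "integral_intensity" in grp
            else None
        )
        segments.extend(
            extract_segments(
                grp["frame"].to_numpy(),
                grp["x"].to_numpy(),
                pixel_size_um,
                frame_interval_s,
                soma_side=soma_side,
                min_run=min_run,
                min_step_um=min_step_um,
                intensity=inten,
                track_id=int(tid),
            )
        )
    return segments


def segments_to_frame(segments) -> pd.DataFrame:
    """Segment list as a flat table (one row per segment)."""
    return pd.DataFrame(
        {
            "track_id": [s.track_id for s in segments],
            "direction": [s.direction for s in segments],
            "start_frame": [s.start_frame for s in segments],
            "n_frames": [s.n_frames for s in segments],
            "displacement_um": [s.displacement_um for s in segments],
            "mean_speed": [s.mean_speed for s in segments],
            "mean_intensity": [s.mean_intensity for s in segments],
        }
    )


def direction_stats(segments) -> dict[str, DirectionStats]:
    """Per-direction means, SEMs, movement-event counts and flux.

    A movement event is one frame-to-frame step inside a processive
    segment; the flux of a direction is its mean speed multiplied by its
    number of movement events.  Directions with no segments are omitted
    (undefined, not zero).
    """
    out: dict[str, DirectionStats] = {}
    for direction in (RETROGRADE, ANTEROGRADE):
        sel = [s for s in segments if s.direction == direction]
        if not sel:
            continue
        disp = np.array([s.displacement_um for s in sel])
        speeds = np.concatenate([s.step_speeds for s in sel])
        n_events = int(sum(s.n_frames - 1 for s in sel))
        out[direction] = DirectionStats(
            direction=direction,
            n_segments=len(sel),
            n_movement_events=n_events,
            mean_displacement_um=float(disp.mean()),
            sem_displacement_um=_sem(disp),
            mean_speed_um_s=float(speeds.mean()),
            sem_speed_um_s=_sem(speeds),
            flux=float(speeds.mean() * n_events),
        )
    return out


def compare_groups(sample_a, sample_b) -> dict[str, float]:
    """Two-sample Student's t comparison of two speed samples.

    Returns both the equal-variance Student statistic and the Welch
    variant.  Two identical constant samples compare as p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "t_welch": 0.0, "p_welch": 1.0}
        return {"t": np.inf, "p": 0.0, "t_welch": np.inf, "p_welch": 0.0}
    t_eq, p_eq = stats.ttest_ind(a, b, equal_var=True)
    t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t_eq),
        "p": float(p_eq),
        "t_welch": float(t_w),
        "p_welch": float(p_w),
    }
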