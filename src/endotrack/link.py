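"""Frame-to-frame track association with LAP-style assignment.

Detections are associated into tracks transition by transition: for each
frame the assignment between existing track ends and new detections
minimises the total squared displacement cost over all detections of that
transition simultaneously (global in space), with explicit birth and
death alternatives, while only a bounded temporal look-back of track ends
is considered (local in time).  Candidate pairs whose implied speed
exceeds ``max_speed_um_s`` are inadmissible.  Track ends unmatched for up
to ``max_gap`` frames may be re-linked, with the missing frames filled by
linear interpolation and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

__all__ = ["TrackLinker", "link_tracks", "pair_channels", "double_positive_fraction"]

_INF = 1e12


@dataclass
class _ActiveTrack:
    track_id: int
    rows: list = field(default_factory=list)  # row dicts
    last_frame: int = -1
    x: float = 0.0
    y: float = 0.0


class TrackLinker(BaseEstimator):
    """LAP-style detection-to-track association.

    Parameters
    ----------
    max_speed_um_s : float
        Hard admissibility bound on frame-to-frame speed (default 10, the
        upper end of the speed fit range).
    max_gap : int
        Longest tolerated detection gap (frames) closed by interpolation.
    pixel_size_um, frame_interval_s : float
        Calibration used to convert the speed bound into pixels.

    Notes
    -----
    Birth and death both cost ``(max_speed * dt)^2`` (in µm²), the standard
    LAP construction: linking farther than one frame-interval at top speed
    is never preferred over a death+birth pair.

    Attributes
    ----------
    tracks_ : pandas.DataFrame
        Columns track_id, frame, x, y, integral_intensity, interpolated.
    cost_ : float
        Total achieved objective (matched squared displacements in µm²
        plus birth/death penalties), summed over transitions.
    """

    def __init__(
        self,
        max_speed_um_s: float = 10.0,
        max_gap: int = 0,
        pixel_size_um: float = 0.167,
        frame_interval_s: float = 0.33,
    ):
        self.max_speed_um_s = max_speed_um_s
        self.max_gap = max_gap
        self.pixel_size_um = pixel_size_um
        self.frame_interval_s = frame_interval_s

    def fit(self, detections: pd.DataFrame, y=None):
        """Link a detection table (columns frame, x, y, ...) into tracks."""
        if self.max_speed_um_s <= 0:
            raise ValueError("max_speed_um_s must be positive")
        cols = ["track_id", "frame", "x", "y", "integral_intensity", "interpolated"]
        if detections is None or len(detections) == 0:
            self.tracks_ = pd.DataFrame(columns=cols)
            self.cost_ = 0.0
            return self
        det = detections.sort_values(["frame", "y", "x"], kind="stable")
        frames = np.arange(det["frame"].min(), det["frame"].max() + 1)
        px = self.pixel_size_um
        b = (self.max_speed_um_s * self.frame_interval_s) ** 2  # birth/death, µm²

        active: list[_ActiveTrack] = []
        finished: list[_ActiveTrack] = []
        next_id = 0
        total_cost = 0.0
        by_frame = dict(tuple(det.groupby("frame")))

        def new_track(row, frame):
            nonlocal next_id
            tr = _ActiveTrack(track_id=next_id)
            next_id += 1
            tr.rows.append(self._row(tr.track_id, frame, row, False))
            tr.last_frame = frame
            tr.x, tr.y = float(row["x"]), float(row["y"])
            return tr

        first = True
        for f in frames:
            grp = by_frame.get(f)
            dets = grp.to_dict("records") if grp is not None else []
            if first:
                for row in dets:
                    active.append(new_track(row, int(f)))
                first = False
                continue
            n, m = len(active), len(dets)
            if n + m:
                total_cost += self._assign(active, dets, int(f), b, px, new_track)
            # retire ends whose gap exceeded max_gap
            still = []
            for tr in active:
                if int(f) - tr.last_frame > self.max_gap:
                    finished.append(tr)
                else:
                    still.append(tr)
            active = still
        finished.extend(active)
        rows = [r for tr in finished for r in tr.rows]
        self.tracks_ = (
            pd.DataFrame(rows, columns=cols)
            .sort_values(["track_id", "frame"])
            .reset_index(drop=True)
        )
        self.cost_ = float(total_cost)
        return self

    @staticmethod
    def _row(tid, frame, row, interp):
        return {
            "track_id": tid,
            "frame": frame,
            "x": float(row["x"]),
            "y": float(row["y"]),
            "integral_intensity": float(row.get("integral_intensity", np.nan)),
            "interpolated": bool(interp),
        }

    def _assign(self, active, dets, f, b, px, new_track):
        """One transition: ends x detections LAP with birth/death dummies."""
        n, m = len(active), len(dets)
        dt = self.frame_interval_s
        size = n + m
        C = np.full((size, size), 0.0)
        C[:n, :m] = _INF
        C[:n, m:] = _INF
        C[n:, :m] = _INF
        for i, tr in enumerate(active):
            gap = f - tr.last_frame  # >= 1
            max_d2 = (self.max_speed_um_s * dt * gap) ** 2
            for j, d in enumerate(dets):
                d2 = ((tr.x - d["x"]) ** 2 + (tr.y - d["y"]) ** 2) * px**2
                if d2 <= max_d2:
                    C[i, j] = d2
            C[i, m + i] = b  # death
        for j in range(m):
            C[n + j, j] = b  # birth
        # lower-right block stays 0: dummy-dummy pairings are free
        rr, cc = linear_sum_assignment(C)
        cost = 0.0
        matched_dets = set()
        for i, j in zip(rr, cc):
            if i < n and j < m and C[i, j] < _INF:
                tr, d = active[i], dets[j]
                gap = f - tr.last_frame
                for g in range(1, gap):  # interpolate closed gaps
                    frac = g / gap
                    tr.rows.append(
                        self._row(
                            tr.track_id,
                            tr.last_frame + g,
                            {
                                "x": tr.x + frac * (d["x"] - tr.x),
                                "y": tr.y + frac * (d["y"] - tr.y),
                                "integral_intensity": np.nan,
                            },
                            True,
                        )
                    )
                tr.rows.append(self._row(tr.track_id, f, d, False))
                tr.last_frame = f
                tr.x, tr.y = float(d["x"]), float(d["y"])
                matched_dets.add(j)
                cost += C[i, j]
            elif i < n and j >= m:
                cost += b  # death (end unmatched this transition)
            elif i >= n and j < m:
                cost += b  # birth
        for j, d in enumerate(dets):
            if j not in matched_dets:
                active.append(new_track(d, f))
        return cost

    def transform(self, detections: pd.DataFrame) -> pd.DataFrame:
        return self.fit(detections).tracks_


def link_tracks(
    detections: pd.DataFrame,
    max_speed_um_s: float = 10.0,
    max_gap: int = 0,
    pixel_size_um: float = 0.167,
    frame_interval_s: float = 0.33,
) -> pd.DataFrame:
    """Associate per-frame detections into tracks; see :class:`TrackLinker`."""
    return TrackLinker(
        max_speed_um_s=max_speed_um_s,
        max_gap=max_gap,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    ).fit(detections).tracks_


def pair_channels(
    tracks: pd.DataFrame,
    restored_b,
    radius_px: float = 3.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Measure the second-channel intensity along channel-A tracks.

    For every detection of the channel-A tracks the channel-B differential
    intensity within ``radius_px`` of the position is summed; if it is not
    significant against the propagated channel-B uncertainty at level
    ``alpha`` it is reported as 0.  Returns the track table with
    ``channelB_intensity`` and ``channelB_significant`` columns appended.
    """
    from scipy import special

    diff = restored_b.differential
    sd = restored_b.differential_sd
    T, H, W = diff.shape
    yy, xx = np.mgrid[0:H, 0:W]
    out_int = np.zeros(len(tracks))
    out_sig = np.zeros(len(tracks), dtype=bool)
    for idx, row in enumerate(tracks.itertuples(index=False)):
        t = int(row.frame)
        if not 0 <= t < T:
            raise ValueError(f"track frame {t} outside channel-B movie")
        mask = (xx - row.x) ** 2 + (yy - row.y) ** 2 <= radius_px**2
        s = float(diff[t][mask].sum())
        noise = float(np.sqrt((sd[t][mask] ** 2).sum()))
        p = float(special.ndtr(-s / max(noise, 1e-12)))
        if p < alpha:
            out_int[idx] = s
            out_sig[idx] = True
    out = tracks.copy()
    out["channelB_intensity"] = out_int
    out["channelB_significant"] = out_sig
    return out


def double_positive_fraction(paired: pd.DataFrame, min_frame_fraction: float = 0.5):
    """Fraction of tracks significant in channel B at >= the given
    fraction of their frames."""
    if len(paired) == 0:
        return 0.0, 0
    per_track = paired.groupby("track_id")["channelB_significant"].mean()
    n_pos = int((per_track >= min_frame_fraction).sum())
    return n_pos / len(per_track), n_pos
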