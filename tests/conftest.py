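"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import endotrack as et


@pytest.fixture(scope="session")
def default_model():
    return et.MotionModel()


@pytest.fixture(scope="session")
def small_movie():
    """A modest two-state movie used by several stages (rendered once)."""
    movie, truth, cfg = et.make_movie(n_endosomes=8, n_frames=60, seed=1)
    return movie, truth, cfg


@pytest.fixture(scope="session")
def restored_small(small_movie):
    movie, truth, cfg = small_movie
    return et.BFBDFilter().transform(movie), truth, cfg


# ---------------------------------------------------------------------------
# oracles

def truth_fast_runs(truth, min_frames=4):
    """Ground-truth fast runs (state label != slow), as frame/position arrays.

    A run labelled over steps i..j spans frames fr[i]..fr[j]+1 inclusive.
    """
    runs = []
    for tid, g in truth.tracks.groupby("track_id"):
        g = g.sort_values("frame")
        st = g["state"].to_numpy()
        fr = g["frame"].to_numpy()
        x = g["x_px"].to_numpy()
        y = g["y_px"].to_numpy()
        fast = st != "slow"
        i = 0
        while i < len(fast):
            if fast[i]:
                j = i
                while j + 1 < len(fast) and fast[j + 1] and st[j + 1] == st[i]:
                    j += 1
                if (j - i + 2) >= min_frames:
                    runs.append(
                        dict(
                            tid=tid,
                            frames=fr[i : j + 2],
                            xs=x[i : j + 2],
                            ys=y[i : j + 2],
                        )
                    )
                i = j + 1
            else:
                i += 1
    return runs


def run_recovery_fraction(tracks: pd.DataFrame, runs, tol_px=2.0, min_overlap=0.5):
    """Fraction of ground-truth fast runs matched by some detected track:
    a run is recovered if one track covers >= min_overlap of its frames
    with mean position error <= tol_px."""
    if not runs:
        return float("nan")
    track_groups = [
        g.sort_values("frame") for _, g in tracks.groupby("track_id")
    ]
    got = 0
    for run in runs:
        frames = run["frames"]
        pos = {f: (xx, yy) for f, xx, yy in zip(frames, run["xs"], run["ys"])}
        for g in track_groups:
            common = np.intersect1d(g["frame"].to_numpy(), frames)
            if len(common) < min_overlap * len(frames):
                continue
            sel = g[g["frame"].isin(common)]
            err = np.hypot(
                sel["x"].to_numpy() - [pos[f][0] for f in sel["frame"]],
                sel["y"].to_numpy() - [pos[f][1] for f in sel["frame"]],
            )
            if err.mean() <= tol_px:
                got += 1
                break
    return got / len(runs)


def brute_force_segments(
    frames, x_px, pixel_size_um, frame_interval_s, min_run=4, min_step_um=None
):
    """Exhaustive scan over all windows for maximal unidirectional runs."""
    frames = np.asarray(frames)
    x_um = np.asarray(x_px, dtype=float) * pixel_size_um
    if min_step_um is None:
        min_step_um = 0.5 * pixel_size_um
    n = len(frames)
    dx = np.diff(x_um)
    ok = (np.abs(dx) >= min_step_um) & (np.diff(frames) == 1)
    sgn = np.sign(dx)

    def window_valid(i, j):  # steps i..j inclusive
        return all(ok[t] and sgn[t] == sgn[i] for t in range(i, j + 1))

    out = []
    for i in range(n - 1):
        for j in range(i, n - 1):
            if not window_valid(i, j):
                continue
            # maximal: cannot extend either side
            if i > 0 and window_valid(i - 1, j):
                continue
            if j < n - 2 and window_valid(i, j + 1):
                continue
            if (j - i + 1) >= min_run - 1:
                out.append((int(frames[i]), j - i + 2, float(np.abs(dx[i : j + 1]).sum())))
    return sorted(out)


def brute_force_link_cost(frames_dets, birth_cost, pixel_size_um):
    """Exhaustive optimum of the per-transition linking objective
    (valid oracle when max_gap = 0, where transitions decouple)."""
    import itertools

    total = 0.0
    for t in range(1, len(frames_dets)):
        prev, cur = frames_dets[t - 1], frames_dets[t]
        n, m = len(prev), len(cur)
        best = None
        for r in range(0, min(n, m) + 1):
            for prev_idx in itertools.combinations(range(n), r):
                for cur_idx in itertools.permutations(range(m), r):
                    c = 0.0
                    feasible = True
                    for i, j in zip(prev_idx, cur_idx):
                        d2 = (
                            (prev[i][0] - cur[j][0]) ** 2
                            + (prev[i][1] - cur[j][1]) ** 2
                        ) * pixel_size_um**2
                        if d2 > birth_cost:
                            feasible = False
                            break
                        c += d2
                    if not feasible:
                        continue
                    c += birth_cost * (n - r) + birth_cost * (m - r)
                    if best is None or c < best:
                        best = c
        total += best
    return total
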