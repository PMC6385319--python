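"""Track association: LAP optimality, gap closing, channel pairing."""

import numpy as np
import pandas as pd
import pytest

import endotrack as et
from conftest import brute_force_link_cost

PX, DT = 0.167, 0.33


def det_frame(rows):
    return pd.DataFrame(rows, columns=["frame", "x", "y", "integral_intensity"])


class TestLinkTracks:
    def test_two_parallel_tracks(self):
        rows = []
        for t in range(10):
            rows.append((t, 5.0 + t, 5.0, 1.0))
            rows.append((t, 5.0 + t, 20.0, 1.0))
        tracks = et.link_tracks(det_frame(rows), pixel_size_um=PX, frame_interval_s=DT)
        assert tracks["track_id"].nunique() == 2
        assert (tracks.groupby("track_id").size() == 10).all()

    def test_gap_closed_with_interpolation(self):
        rows = [(t, 5.0 + t, 8.0, 1.0) for t in range(10) if t != 5]
        tracks = et.link_tracks(
            det_frame(rows), max_gap=1, pixel_size_um=PX, frame_interval_s=DT
        )
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 10
        interp = tracks[tracks["interpolated"]]
        assert list(interp["frame"]) == [5]
        assert interp.iloc[0].x == pytest.approx(10.0)

    def test_empty_input(self):
        tracks = et.link_tracks(pd.DataFrame(columns=["frame", "x", "y"]))
        assert tracks.empty

    def test_speed_bound_prevents_link(self):
        """A jump faster than max_speed starts a new track."""
        rows = [(0, 5.0, 5.0, 1.0), (1, 60.0, 5.0, 1.0)]
        tracks = et.link_tracks(
            det_frame(rows), max_speed_um_s=10.0, pixel_size_um=PX, frame_interval_s=DT
        )
        assert tracks["track_id"].nunique() == 2

    def test_oracle_equivalence_on_random_instances(self):
        """Achieved objective equals exhaustive enumeration on 50 random
        small instances (<=4 detections/frame, <=6 frames, max_gap=0)."""
        rng = np.random.default_rng(0)
        b = (10.0 * DT) ** 2
        for _ in range(50):
            T = int(rng.integers(2, 7))
            frames_dets, rows = [], []
            for t in range(T):
                m = int(rng.integers(0, 5))
                pts = rng.uniform(0, 30, size=(m, 2))
                frames_dets.append([tuple(p) for p in pts])
                rows += [(t, p[0], p[1], 1.0) for p in pts]
            if not rows:
                continue
            linker = et.TrackLinker(
                max_speed_um_s=10.0, max_gap=0, pixel_size_um=PX, frame_interval_s=DT
            ).fit(det_frame(rows))
            fmin = min(r[0] for r in rows)
            fmax = max(r[0] for r in rows)
            oracle = brute_force_link_cost(frames_dets[fmin : fmax + 1], b, PX)
            assert linker.cost_ == pytest.approx(oracle, abs=1e-9)

    def test_detection_conservation(self):
        """Every detection belongs to exactly one track."""
        rng = np.random.default_rng(2)
        rows = [
            (t, float(rng.uniform(0, 50)), float(rng.uniform(0, 20)), 1.0)
            for t in range(8)
            for _ in range(rng.integers(1, 4))
        ]
        det = det_frame(rows)
        tracks = et.link_tracks(det, pixel_size_um=PX, frame_interval_s=DT)
        real = tracks[~tracks["interpolated"]]
        assert len(real) == len(det)
        got = sorted(map(tuple, real[["frame", "x", "y"]].to_numpy().tolist()))
        want = sorted(map(tuple, det[["frame", "x", "y"]].to_numpy().tolist()))
        assert got == want

    def test_detection_order_permutation_invariant(self):
        rng = np.random.default_rng(7)
        rows = [
            (t, float(rng.uniform(0, 40)), float(rng.uniform(0, 20)), 1.0)
            for t in range(6)
            for _ in range(3)
        ]
        det = det_frame(rows)
        t1 = et.link_tracks(det, pixel_size_um=PX, frame_interval_s=DT)
        det_shuffled = det.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t2 = et.link_tracks(det_shuffled, pixel_size_um=PX, frame_interval_s=DT)

        def membership(tr):
            return sorted(
                tuple(sorted(map(tuple, g[["frame", "x", "y"]].to_numpy().tolist())))
                for _, g in tr[~tr["interpolated"]].groupby("track_id")
            )

        assert membership(t1) == membership(t2)


class TestPairChannels:
    def test_identical_channels_all_double_positive(self, restored_small):
        res, truth, cfg = restored_small
        det = et.SpotDetector(alpha=0.01).detect_movie(res)
        tracks = et.TrackLinker(
            max_gap=1, pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s
        ).fit(det).tracks_
        paired = et.pair_channels(tracks, res, radius_px=3.0)
        frac, n = et.double_positive_fraction(paired)
        assert frac > 0.9

    def test_empty_channel_b_zero_double_positive(self, restored_small):
        res, truth, cfg = restored_small
        det = et.SpotDetector(alpha=0.01).detect_movie(res)
        tracks = et.TrackLinker(
            max_gap=1, pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s
        ).fit(det).tracks_
        rng = np.random.default_rng(0)
        from endotrack.restore import RestoredMovie

        shape = res.differential.shape
        empty = RestoredMovie(
            denoised=np.zeros(shape),
            background=np.zeros(shape),
            differential=rng.normal(0, 1.0, shape),
            differential_sd=np.ones(shape),
        )
        paired = et.pair_channels(tracks, empty, radius_px=3.0)
        frac, n = et.double_positive_fraction(paired)
        assert n == 0

    def test_partial_colabel_fraction_recovered(self):
        """A 30% co-labelled population yields a double-positive fraction
        within binomial error of 30%."""
        model = et.MotionModel(p_slow_to_fast=0.25)  # keep endosomes moving
        cfg = et.SimulationConfig(n_frames=50, n_endosomes=20, seed=21)
        truth = et.simulate_tracks(model, cfg)
        ids = sorted(truth.tracks["track_id"].unique())
        co = ids[:6]  # 30% of 20
        movie_a = et.render_movie(truth, cfg)
        cfg_b = et.SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000})
        movie_b = et.render_movie(et.subset_truth(truth, co), cfg_b)
        res_a = et.BFBDFilter().transform(movie_a)
        res_b = et.BFBDFilter().transform(movie_b)
        det = et.SpotDetector(alpha=0.01).detect_movie(res_a)
        tracks = et.TrackLinker(
            max_gap=1, pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s
        ).fit(det).tracks_
        paired = et.pair_channels(tracks, res_b, radius_px=3.0)
        frac, _ = et.double_positive_fraction(paired)
        assert 0.3 == pytest.approx(frac, abs=2 * np.sqrt(0.3 * 0.7 / 20) + 0.05)

    def test_shape_mismatch_rejected(self, restored_small):
        res, truth, cfg = restored_small
        tracks = pd.DataFrame(
            {"track_id": [0], "frame": [9999], "x": [5.0], "y": [5.0]}
        )
        with pytest.raises(ValueError, match="outside"):
            et.pair_channels(tracks, res)
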