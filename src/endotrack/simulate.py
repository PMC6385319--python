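"""Ground-truthed synthetic axonal movies, track tables and FLIM stacks.

No raw movies accompany the motility analysis this package implements, so
every downstream stage is exercised on synthetic data with the statistical
structure the analysis assumes:

* point-like endosomes moving along a 1-D axon axis with a two-state
  motion model — a slow oscillatory state (zero-mean random walk with
  log-normal step speeds) and fast processive runs of at least
  ``min_run_frames`` frames whose per-step speeds are log-normal, with a
  configurable retrograde bias of run initiation;
* log-normal integral intensities per endosome, optionally rank-coupled to
  the propensity to start fast runs (brighter endosomes run more);
* diffraction-limited spots rendered with the same squared-Lorentzian
  profile the detector fits, on a slowly varying cytosolic background with
  Poisson + Gaussian camera noise;
* time-gated fluorescence decay stacks with per-region monoexponential
  lifetimes.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flim import DecayStack

__all__ = [
    "MotionModel",
    "SimulationConfig",
    "GroundTruth",
    "FlimSimConfig",
    "simulate_tracks",
    "render_movie",
    "simulate_flim_stack",
    "make_tracks",
    "make_movie",
    "make_flim_stack",
    "subset_truth",
    "squared_lorentzian_frame",
]

SLOW = "slow"
FAST_RETRO = "fast-retro"
FAST_ANTERO = "fast-antero"


@dataclass
class MotionModel:
    """Two-state (slow oscillatory / fast processive) axial motion model.

    Speeds are log-normal: a state with parameters (mu, sigma) draws
    per-step speeds from LogNormal(ln mu, sigma), so the state's mean
    speed is mu * exp(sigma**2 / 2).  Defaults correspond to a slow
    component around 0.33 µm/s and a fast retrograde component around
    1.6 µm/s median scale, with a retrograde bias of run initiation.
    """

    p_slow_to_fast: float = 0.04
    p_fast_to_slow: float = 0.25
    retro_bias: float = 0.75
    slow_mu: float = 0.33
    slow_sigma: float = 0.98
    fast_mu_retro: float = 1.6
    fast_sigma_retro: float = 0.57
    fast_mu_antero: float = 1.8
    fast_sigma_antero: float = 0.13
    min_run_frames: int = 4

    def validate(self):
        for name in ("p_slow_to_fast", "p_fast_to_slow", "retro_bias"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        for name in ("slow_mu", "fast_mu_retro", "fast_mu_antero"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        for name in ("slow_sigma", "fast_sigma_retro", "fast_sigma_antero"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0 and finite, got {v!r}")
        if self.min_run_frames < 4:
            raise ValueError("min_run_frames must be >= 4")


@dataclass
class SimulationConfig:
    """Acquisition geometry, intensity statistics and camera noise."""

    axon_length_px: int = 256
    image_height_px: int = 32
    pixel_size_um: float = 0.167
    frame_interval_s: float = 0.33  # 3 frames per second
    n_frames: int = 100
    n_endosomes: int = 12
    intensity_mu: float = 450.0
    intensity_sigma: float = 0.3
    intensity_motility_coupling: float = 0.0
    psf_width_px: float = 1.7
    background: str = "constant"  # constant | gradient | bilinear | slow_drift
    background_amplitude: float = 20.0
    gaussian_noise_sd: float = 2.0
    poisson_scaling: float = 1.0  # photons per count; 0 disables shot noise
    soma_side: str = "left"
    seed: int = 0

    def validate(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not -1 <= self.intensity_motility_coupling <= 1:
            raise ValueError("intensity_motility_coupling must be in [-1, 1]")
        if self.soma_side not in ("left", "right"):
            raise ValueError("soma_side must be 'left' or 'right'")


@dataclass
class GroundTruth:
    """Per-endosome time series with state labels and the soma side.

    ``tracks`` columns: track_id, frame, x_px, y_px, state, intensity.
    """

    tracks: pd.DataFrame
    soma_side: str = "left"

    def n_endosomes(self) -> int:
        return 0 if self.tracks.empty else self.tracks["track_id"].nunique()


@dataclass
class FlimSimConfig:
    """Gated-decay simulation: per-region lifetime and amplitude maps."""

    n_gates: int = 16
    gate_step_ps: float = 500.0
    tau_map: np.ndarray | float = 2.5  # ns; scalar or (H, W)
    amplitude_map: np.ndarray | float = 1000.0  # a.u.; scalar or (H, W)
    shape: tuple[int, int] = (32, 32)
    background_level: float = 0.0
    poisson_noise: bool = False
    gaussian_noise_sd: float = 0.0
    seed: int = 0

    def validate(self):
        if self.n_gates < 3:
            raise ValueError("n_gates must be >= 3")
        tau = np.asarray(self.tau_map, dtype=float)
        if np.any(tau <= 0) or not np.all(np.isfinite(tau)):
            raise ValueError("all lifetimes must be positive and finite")


def _fast_run_lengths(rng, p_stop, n, min_run):
    """Run duration (frames) = min_run + Geometric(p_stop) extra frames."""
    if p_stop <= 0:
        return np.full(n, 10**6)
    return min_run + rng.geometric(p_stop, size=n) - 1


def simulate_tracks(model: MotionModel, config: SimulationConfig) -> GroundTruth:
    """Simulate per-frame endosome positions, states and intensities.

    Fast runs last at least ``model.min_run_frames`` frames and their
    per-frame displacements are speed * frame_interval with the speed
    drawn from the run direction's log-normal.  The slow state is a
    zero-mean random walk with log-normal step speeds and random sign.
    Positive ``intensity_motility_coupling`` makes brighter endosomes
    (by intensity rank) initiate fast runs more often.
    """
    model.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_endosomes, config.n_frames
    if n == 0:
        cols = ["track_id", "frame", "x_px", "y_px", "state", "intensity"]
        return GroundTruth(pd.DataFrame(columns=cols), soma_side=config.soma_side)

    px = config.pixel_size_um
    dt = config.frame_interval_s
    W, H = config.axon_length_px, config.image_height_px

    intensities = rng.lognormal(math.log(config.intensity_mu), config.intensity_sigma, n)
    # rank-couple fast-run initiation to intensity
    ranks = np.argsort(np.argsort(intensities)) / max(n - 1, 1)
    c = config.intensity_motility_coupling
    p_init = model.p_slow_to_fast * (1.0 + c * (2.0 * ranks - 1.0))
    p_init = np.clip(p_init, 0.0, 1.0)

    rows = []
    margin = 4.0
    for i in range(n):
        x = rng.uniform(margin, W - margin)
        y = rng.uniform(margin, H - margin)
        state = SLOW
        run_left = 0  # fast steps remaining in the current run
        direction = 0
        for t in range(T):
            # maybe initiate a fast run; the frame label is the state of
            # the step leaving this frame
            if state == SLOW and t < T - 1 and rng.random() < p_init[i]:
                retro = rng.random() < model.retro_bias
                direction = -1 if retro else 1
                if config.soma_side == "right":
                    direction = -direction
                state = FAST_RETRO if retro else FAST_ANTERO
                # run duration in frames >= min_run_frames, so in steps
                # >= min_run_frames - 1
                run_frames = int(
                    _fast_run_lengths(
                        rng, model.p_fast_to_slow, 1, model.min_run_frames
                    )[0]
                )
                run_left = run_frames - 1
            rows.append((i, t, x, y, state, intensities[i]))
            if t == T - 1:
                break
            if state == SLOW:
                speed = rng.lognormal(math.log(model.slow_mu), model.slow_sigma)
                step = speed * dt / px * (1 if rng.random() < 0.5 else -1)
            else:
                retro = state == FAST_RETRO
                mu = model.fast_mu_retro if retro else model.fast_mu_antero
                sig = model.fast_sigma_retro if retro else model.fast_sigma_antero
                speed = rng.lognormal(math.log(mu), sig)
                step = direction * speed * dt / px
                run_left -= 1
            x_new = x + step
            # clamp at the axon ends; a clamped fast run is terminated
            if x_new < margin or x_new > W - margin:
                x_new = float(np.clip(x_new, margin, W - margin))
                run_left = 0
            x = x_new
            y = float(np.clip(y + rng.normal(0, 0.05), 1.0, H - 1.0))
            if state != SLOW and run_left <= 0:
                state = SLOW
    df = pd.DataFrame(
        rows, columns=["track_id", "frame", "x_px", "y_px", "state", "intensity"]
    )
    return GroundTruth(df, soma_side=config.soma_side)


def squared_lorentzian_frame(shape, x0, y0, w, integral_intensity):
    """Render one spot as A / (1 + r^2/w^2)^2 with analytic integral
    A * pi * w^2 equal to ``integral_intensity``."""
    H, W = shape
    A = integral_intensity / (math.pi * w * w)
    yy, xx = np.mgrid[0:H, 0:W]
    r2 = (xx - x0) ** 2 + (yy - y0) ** 2
    return A / (1.0 + r2 / (w * w)) ** 2


def _background_frame(config: SimulationConfig, t: int) -> np.ndarray:
    H, W = config.image_height_px, config.axon_length_px
    amp = config.background_amplitude
    yy, xx = np.mgrid[0:H, 0:W]
    kind = config.background
    if kind == "constant":
        return np.full((H, W), amp, dtype=float)
    if kind == "gradient":
        return amp * (0.5 + xx / max(W - 1, 1))
    if kind == "bilinear":
        u, v = xx / max(W - 1, 1), yy / max(H - 1, 1)
        return amp * (0.5 + 0.5 * u + 0.3 * v + 0.4 * u * v)
    if kind == "slow_drift":
        phase = 2 * math.pi * t / max(config.n_frames, 1)
        return amp * (1.0 + 0.2 * math.sin(phase)) * (0.5 + 0.5 * xx / max(W - 1, 1))
    raise ValueError(f"unknown background kind {kind!r}")


def render_movie(truth: GroundTruth, config: SimulationConfig) -> np.ndarray:
    """Render the ground truth into a (n_frames, H, W) movie stack.

    Spots use the same squared-Lorentzian profile the detector fits,
    scaled so the analytic integral equals the endosome intensity.
    Background and Poisson + Gaussian noise are added per config;
    the output is deterministic for a given config seed.
    """
    config.validate()
    if config.psf_width_px <= 0:
        raise ValueError("psf_width_px must be positive")
    H, W = config.image_height_px, config.axon_length_px
    T = config.n_frames
    rng = np.random.default_rng(config.seed + 1)  # noise stream
    movie = np.empty((T, H, W), dtype=float)
    tr = truth.tracks
    by_frame = dict(tuple(tr.groupby("frame"))) if not tr.empty else {}
    for t in range(T):
        frame = _background_frame(config, t)
        grp = by_frame.get(t)
        if grp is not None:
            for _, row in grp.iterrows():
                frame += squared_lorentzian_frame(
                    (H, W),
                    row["x_px"],
                    row["y_px"],
                    config.psf_width_px,
                    row["intensity"],
                )
        if config.poisson_scaling > 0:
            lam = np.clip(frame * config.poisson_scaling, 0, None)
            frame = rng.poisson(lam).astype(float) / config.poisson_scaling
        if config.gaussian_noise_sd > 0:
            frame = frame + rng.normal(0, config.gaussian_noise_sd, size=(H, W))
        movie[t] = frame
    return movie


def simulate_flim_stack(config: FlimSimConfig) -> DecayStack:
    """Gated decay stack: gate g = A * exp(-t_g / tau) + background (+noise),
    with t_g = g * gate_step."""
    config.validate()
    H, W = config.shape
    tau = np.broadcast_to(np.asarray(config.tau_map, dtype=float), (H, W))
    A = np.broadcast_to(np.asarray(config.amplitude_map, dtype=float), (H, W))
    step_ns = config.gate_step_ps / 1000.0
    t = np.arange(config.n_gates) * step_ns
    gates = A[None] * np.exp(-t[:, None, None] / tau[None]) + config.background_level
    rng = np.random.default_rng(config.seed)
    if config.poisson_noise:
        gates = rng.poisson(np.clip(gates, 0, None)).astype(float)
    if config.gaussian_noise_sd > 0:
        gates = gates + rng.normal(0, config.gaussian_noise_sd, size=gates.shape)
    return DecayStack(gates=gates, gate_times_ns=t)


def subset_truth(truth: GroundTruth, track_ids) -> GroundTruth:
    """Ground truth restricted to a subset of endosomes (e.g. the
    co-labeled population of a second channel)."""
    sel = truth.tracks[truth.tracks["track_id"].isin(list(track_ids))]
    return GroundTruth(sel.reset_index(drop=True), soma_side=truth.soma_side)


# sklearn-style convenience constructors ------------------------------------

def make_tracks(
    model: MotionModel | None = None, config: SimulationConfig | None = None, **kw
) -> GroundTruth:
    """Ground-truth tracks with default model/config; kwargs override config."""
    model = model or MotionModel()
    config = config or SimulationConfig(**kw)
    return simulate_tracks(model, config)


def make_movie(
    model: MotionModel | None = None, config: SimulationConfig | None = None, **kw
):
    """(movie, truth, config) with defaults; kwargs override config fields."""
    model = model or MotionModel()
    config = config or SimulationConfig(**kw)
    truth = simulate_tracks(model, config)
    return render_movie(truth, config), truth, config


def make_flim_stack(**kw) -> DecayStack:
    return simulate_flim_stack(FlimSimConfig(**kw))
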