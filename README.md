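# endotrack

Quantitative analysis of axonal signaling-endosome motility from
fluorescence time-lapse movies, plus time-gated FLIM/FRET lifetime
analysis — the full chain from raw (or synthetic) two-channel image
stacks to direction-resolved speed statistics.

Neurons transport endosomes carrying neurotrophin receptors (TrkB), early
endosome markers (Rab5), adaptors (APPL1) and kinases (Akt1) along their
axons, either *retrogradely* (toward the cell body) or *anterogradely*
(toward the growth cone). Quantifying how fast, how far, and in which
direction these endosomes move — and how that depends on how much marker
each endosome carries — requires a pipeline of image restoration, sub-pixel
spot detection, track linking and statistical decomposition. This package
implements that pipeline for researchers analysing axonal-transport movies
acquired at a few frames per second, and for method developers who need a
fully synthetic, ground-truthed test bed.

## The pipeline

1. **Synthetic data** (`endotrack.simulate`): a two-state motion model
   (slow oscillatory state / fast processive runs of ≥ 4 frames with
   log-normally distributed speeds and a configurable retrograde bias)
   rendered into movies with diffraction-limited squared-Lorentzian spots,
   slowly varying cytosolic background and Poisson + Gaussian camera
   noise; plus gated monoexponential FLIM stacks. All deterministic per
   seed.
2. **Background discrimination** (`BFBDFilter`): per-pixel temporal split
   of each movie into a slowly varying background (exponential-forgetting
   posterior mean) and a differential image with propagated uncertainty —
   this reveals dim *moving* endosomes inside bright cytoplasm. An
   optional XY-bilinear surface fit removes large smooth gradients.
3. **Spot detection** (`SpotDetector`): sub-pixel fitting of sums of
   squared-Lorentzian profiles `A/(1 + r²/w²)²`; the analytic integral
   `A·π·w²` is the spot's *integral intensity* (marker amount). Noise is
   rejected by probabilistic thresholding at a significance level α.
4. **Track linking** (`TrackLinker`): frame-to-frame linear-assignment
   optimisation with birth/death costs, a hard speed bound, and bounded
   gap closing with interpolation.
5. **Motility statistics** (`endotrack.motility`): maximal processive
   (unidirectional, ≥ 4-frame) runs; per-direction displacements, speeds,
   movement-event counts and fluxes (mean speed × event count); Student's
   t comparisons.
6. **Speed mixture** (`LogNormalMixture`): decomposition of each
   direction's speed histogram (fit range 0.07–10 µm/s) into log-normal
   components with an Occam-razor model-selection criterion. Each
   component is summarised by

   ⟨v⟩ = μ · exp(σ²/2)

   its median-scale parameter μ, shape σ, and event-fraction weight.
   `intensity_binned_analysis` repeats the two-component fit per
   integral-intensity bin to ask whether brighter endosomes move
   differently.
7. **FLIM/FRET** (`endotrack.flim`): per-pixel monoexponential decay fits
   `I(t) = A·e^(−t/τ)` of 16-gate, 500-ps-step stacks after background
   correction; ROI lifetimes and FRET efficiency `E = 1 − τ_DA/τ_D`
   from donor-only vs donor+acceptor lifetimes.

Estimator classes follow scikit-learn conventions (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores), and module
functions are thin wrappers over them.

## Worked example

```python
import endotrack as et

# simulate a ground-truthed axon movie: 10 endosomes, 100 frames at 3 fps
movie, truth, cfg = et.make_movie(n_endosomes=10, n_frames=100, seed=7)

restored = et.BFBDFilter().transform(movie)
detections = et.SpotDetector(alpha=0.01).detect_movie(restored)
tracks = et.TrackLinker(max_gap=2,
                        pixel_size_um=cfg.pixel_size_um,
                        frame_interval_s=cfg.frame_interval_s).fit(detections).tracks_
segments = et.extract_all_segments(tracks, cfg.pixel_size_um,
                                   cfg.frame_interval_s, soma_side="left")
stats = et.direction_stats(segments)
for direction, s in stats.items():
    print(direction, s.n_segments, round(s.mean_speed_um_s, 2),
          s.n_movement_events, round(s.flux, 1))
```

prints

```
retrograde 46 1.35 228 306.9
anterograde 26 1.26 125 157.1
```

— 46 retrograde processive segments at a mean step speed of 1.35 µm/s
over 228 movement events (flux 306.9 µm/s·events), against 26 anterograde
segments with 125 events: the simulated retrograde initiation bias (75%)
shows up directly as a ~2× retrograde event excess.

The mean speed of a fitted fast retrograde component with μ = 1.6 µm/s
and σ = 0.57 is

```python
>>> et.lognormal_mean(1.6, 0.57)
1.8822231960052862
```

A command-line interface mirrors the stages
(`endotrack simulate | restore | detect | link | motility | fitmix |
flim | run-all`).

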