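# Methods

This note documents the models, estimators and numerical choices behind
`endotrack`, and what its synthetic-data tests do and do not demonstrate
about real movies.

## Motion model and synthetic movies

Endosome motion along the axon axis is modelled as a two-state process on
a 1-D track (the axon is a horizontal image strip; the soma side is
configurable, default left, so retrograde = decreasing x):

- **Slow (oscillatory) state**: a zero-mean random walk whose per-step
  speed is LogNormal(ln μ_slow, σ_slow) with a random sign. Defaults
  μ_slow = 0.33 µm/s, σ_slow = 0.98, matching the slow component of
  measured speed mixtures. The slow-state mechanics (random walk) are a
  modelling choice; only its speed distribution is constrained.
- **Fast (processive) state**: initiated from the slow state with
  per-frame probability `p_slow_to_fast` (default 0.04); the run
  direction is retrograde with probability `retro_bias` (default 0.75);
  the run lasts `min_run_frames` (default 4) plus a Geometric
  (`p_fast_to_slow`, default 0.25) number of extra frames, so every fast
  run spans at least 4 unidirectional frames. Per-step speeds are
  LogNormal(ln μ, σ) with direction-specific defaults
  (μ_retro = 1.6 µm/s, σ_retro = 0.57; μ_antero = 1.8 µm/s,
  σ_antero = 0.13). A run that reaches the end of the strip is clamped
  and terminated.

Per-endosome integral intensities are LogNormal(ln 450, 0.3) a.u. and
constant in time. `intensity_motility_coupling` ∈ [−1, 1] rank-couples
intensity to the fast-run initiation probability
(`p_i = p·(1 + c·(2·rank_i − 1))`), emulating a brighter-moves-more
population without changing the marginal speed distributions.

Rendering uses the same squared-Lorentzian profile the detector fits
(width 1.7 px default), scaled so the analytic integral equals the
endosome intensity, over a configurable background (constant, gradient,
bilinear, or slowly drifting), then Poisson noise (scaling 1 count/photon)
and Gaussian read noise (sd 2). With the default intensity scale the
per-spot peak signal-to-noise ratio spans roughly 5–12 — detection is
nontrivial but solvable, which is the design point of the acquisition
noise defaults. Acquisition geometry defaults: 0.167 µm/px and 3 frames
per second (0.33 s interval, the middle of the 2–4 fps acquisition range).

**What the generator does not emulate**: photobleaching, 3-D defocus,
microtubule geometry, vesicle fission/fusion, spatially structured
(striped or punctate) cytoplasmic background, and intensity fluctuations
within a track. Passing tests therefore demonstrate correctness of the
estimators under the stated statistical model, not robustness to every
real-microscopy artefact.

## Background discrimination (BFBD + differential image)

Cytosolic background changes slowly in time; a moving endosome changes a
pixel quickly. Per pixel:

- observation noise σ is estimated robustly from temporal first
  differences (median-of-|Δ| estimator, variance pooled over a 3×3
  neighbourhood — the per-pixel estimator's ~13% sampling error would
  otherwise inflate the differential z-score tails);
- the **background** is an exponential-forgetting (Kalman-style) posterior
  mean with gain 2/(`temporal_window`+1), default window 19 frames, run
  forward and backward; the value used at frame t comes from frames
  outside t±1, so background and observation errors are independent;
- the **denoised observation** is a centre-weighted 3-frame kernel
  (default weights 0.8/0.1/0.1). Heavier smoothing lowers noise but
  smears fast endosomes (a 2 µm/s endosome moves ~4 px between frames at
  3 fps) and was the dominant detection-failure mode in development;
- the **differential** is denoised − background with
  `sd² = var(denoised) + var(background)` propagated exactly.

Under pure noise the differential z-scores are calibrated: the measured
|z| > 3 fraction is ~0.0025 against the Gaussian 0.0027. A known physical
consequence: an endosome that dwells in place longer than the background
window is progressively absorbed into the background and released only
after it moves — so the differential image reveals *moving* endosomes,
and the first frame of a run after a long dwell can be attenuated.

The optional XY-bilinear step fits a + b·x + c·y + d·x·y by least squares
per frame and subtracts it before the temporal split (for heavy smooth
cytoplasmic fluorescence); the surface is added back to the background
estimate so the decomposition invariant holds.

## Spot detection

The spot model is the radially symmetric squared Lorentzian
`I(x,y) = A/(1 + r²/w²)²` with finite analytic integral `A·π·w²`, which
is reported as the spot's integral intensity (the estimate is therefore
unbiased under truncation of the tails). Detection per frame:

1. candidates = 3×3 local maxima of z = differential/differential_sd
   above 2;
2. a linear matched-filter screen at fixed position over widths
   {w₀, 2w₀}: the weighted least-squares amplitude is linear in the data;
   candidates not significant at level α at any scale are dropped (this
   keeps the expensive nonlinear stage off pure noise);
3. surviving candidates are grouped by transitive proximity (3·w₀);
   oversized groups are split into compact subgroups seeded by the
   brightest candidates; each subgroup patch is fit by a sum of k
   squared-Lorentzians with sd-weighted least squares and analytic
   Jacobian, with k chosen by a penalised likelihood (several local
   maxima often belong to one motion-broadened spot);
4. a detection is kept iff the probability of its fitted amplitude
   arising from noise — Gaussian with the amplitude standard error from
   the fit covariance, Bonferroni-corrected by the number of resolution
   elements in the patch — is below α. Fits that wander away from their
   own subgroup's seeds are discarded, and coincident detections are
   deduplicated keeping the brighter (deterministic (frame, y, x)
   ordering).

Both thresholding stages apply α, so the empirical false-positive count
on pure noise stays below α × (number of tested candidates). Amplitude
weighting and sd-weighted residuals are both implemented, reflecting the
two readings of a "weighted" squared-Lorentzian fit.

## Track linking

Frame-to-frame association solves, per transition, a linear assignment
over all current track ends and new detections with cost = squared
displacement (µm²), birth and death alternatives both costing
`(max_speed·Δt)²`, and pairs beyond `max_speed·Δt·(gap+1)` inadmissible
(max_speed default 10 µm/s, the top of the speed fit range). Ends may
stay alive `max_gap` frames; closed gaps are linearly interpolated and
flagged. With `max_gap = 0` the transitions decouple, and the solver is
verified against exhaustive enumeration of all feasible assignment
sequences on random small instances. The look-back window is
`max_gap + 1` frames — local in time, global in space.

Channel pairing measures, at every channel-A track position, the
channel-B differential intensity summed in a disc (default radius 3 px)
and tests it against the propagated channel-B uncertainty; a track is
double-positive when significant in ≥ 50% of its frames (the underlying
"detectable second marker" criterion is not otherwise quantified).

## Processive segments and direction statistics

A processive segment is a maximal run of ≥ `min_run` (default 4)
consecutive frames whose axial steps share a sign and exceed
`min_step_um` (default half a pixel — a dead band against localisation
jitter; no published value exists for it). Direction is projected on the
axon axis only. Displacement is the summed |step| of the run; a movement
event is one step inside a segment; flux per direction = mean step speed
× number of movement events. SEMs are sd/√n. Group comparisons report
both the pooled-variance Student t and the Welch variant, over either
segments or tracks (both groupings are supported because the original
grouping convention is ambiguous).

## Log-normal speed mixtures

Speeds inside [0.07, 10] µm/s are histogrammed on 40 log-spaced bins and
the counts are fit by k = 1..k_max sums of log-normal bin masses with
free amplitudes (Poisson-weighted least squares — a histogram fit, not a
raw-sample likelihood, matching how such speed distributions are usually
deconvolved). k is selected by a penalised likelihood: by default BIC
with n = total event count (the observations are events, not bins);
a Laplace approximation with broad uniform priors is available
(`criterion="laplace"`). Weights are event fractions (amplitude shares),
renormalised over fitted components; component labels slow/fast follow
mean-speed order with ties broken by weight. The component mean is
⟨v⟩ = μ·exp(σ²/2) exactly.

Parameter uncertainty comes from the Gauss-Newton covariance with the
delta method. At n = 2·10⁴ events the sampling uncertainty of an
overlapping two-component mixture concentrates in the slow-μ/weight
direction (~3–6% relative), so recovery to 10% is a typical-case, not a
guaranteed, outcome — the suite pins it with a fixed seed.

The intensity-binned analysis groups movement events by their segment's
mean integral intensity (log-spaced or quantile bins, default floor of
30 events per bin), refits k = 2 per bin seeded from the global fit, and
reports per-bin slow/fast mean speeds, the fast-event fraction, and
fit-derived SEMs.

## FLIM and FRET

Gated stacks (default 16 gates, 500 ps step, t_g = g·step) are
background-corrected by the mean of a signal-free ROI. Each pixel above
`min_counts` (default 5× the background sd) is fit by `A·e^(−t/τ)`: a
variance-weighted linear fit of ln I on t (weights = counts, the Poisson
linearisation) refined by vectorised Gauss-Newton steps in data space.
The printed form of the decay model omits the sign of the exponent; a
growing exponential cannot describe a fluorescence decay, so the
implemented model is the decaying one. Pixels with rising overall signal
are masked and counted. ROI lifetime is the A-weighted mean of τ over
masked pixels with an effective-n SEM (a sum-then-fit alternative exists
via fitting the ROI-summed decay). FRET efficiency is E = 1 − τ_DA/τ_D;
negative values (noise) are returned flagged, not clipped.

Noiseless stacks recover τ exactly (<1e-6 relative); Poisson stacks at
A = 5000 recover τ within 5% for >95% of pixels.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → restore → detect → link → motility →
mixture from a single `PipelineConfig`; every output carries a
12-hex-digit config hash, and identical config+seed reproduces CSV/JSON
outputs byte for byte. All randomness flows from explicit
`numpy.random.default_rng` seeds.

Test problem sizes are chosen for thorough-but-quick runs: the
end-to-end recovery experiment uses 10 endosomes over 100 frames of a
256×32 px strip (≈30 s); the speed-mixture recovery uses 2·10⁴ events;
the linker oracle uses ≤ 4 detections × ≤ 6 frames (where exhaustive
enumeration is exact); lognormal-mean Monte-Carlo checks use 10⁶–2·10⁶
draws. Across random seeds the end-to-end experiment recovers ~80–97%
(mean ≈ 88%) of ground-truth fast runs as trackable segments; the losses
are dominated by run-start background absorption (above) and trajectory
crossings, both inherent to the filter design rather than estimator
defects.

## Known limitations

- The background/foreground split assumes temporally white noise and a
  slowly varying background; flicker or stage drift violate it (no
  registration is performed).
- Quasi-static endosomes are absorbed into the background by design;
  dwell-time statistics are not measurable from the differential image.
- The mixture fit is a binned fit; for very small samples (< ~50 events
  in range) it refuses to run rather than return unstable estimates.
- Only monoexponential decays are fit (no instrument response
  deconvolution, no multi-exponential or phasor analysis).
- Channel registration between the two colours is assumed perfect.
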