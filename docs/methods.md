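# Methods

This note documents the models and procedures implemented in `actinwave`,
the defaults and why they were chosen, the numerical details, and the
limits of what the synthetic-data tests establish.

## Signal model and relative intensity

An ROI trace is the per-frame mean intensity of a square region,
`[x, x+size) × [y, y+size)` in 0-based pixel coordinates. The standard
analysis ROI is 20 × 20 px (2.2 × 2.2 μm at 0.11 μm/px); 5 and 40 px sizes
bracket it for robustness checks, and 15 px is the punctum-tracking size.
Wave cycles are consistent across these sizes; larger ROIs give smoother
peaks by spatial averaging.

Relative intensity is computed in two steps:

1. subtract a scalar background `bg`, the spatiotemporal mean of an ROI
   placed outside the cell (camera offset plus stray light, assumed
   constant over the acquisition);
2. divide by a baseline `b`, the mean of the lowest 50 samples of the
   background-subtracted trace (ties broken by value then index, for
   determinism only).

A correctly normalized oscillatory trace has troughs near 1, and peak
values are used directly as oscillation amplitudes. Taking the lowest
points *after* background subtraction makes the result exactly invariant
under a common gain on signal and background; the alternative order breaks
that identity, which is why this order was chosen. Traces shorter than 50
samples fall back to the lowest 25% of points, with a warning — the
50-point rule presumes recordings of several hundred frames. A
non-positive baseline raises an error rather than producing negative
relative intensities: it is the signature of a background region that was
actually inside the cell.

## Oscillation classification

The classifier operationalizes a "single dominant FFT peak in band"
criterion:

- linear detrend (suppresses bleaching leakage into low frequencies),
  boxcar periodogram, DC bin dropped;
- the dominant in-band peak must have per-bin power ≥ `power_ratio_threshold`
  (default 10) times the median spectral power;
- its *lobe* — power integrated over contiguous bins down to the flanking
  valleys, which absorbs scalloping when the true frequency falls between
  bins — must exceed every other in-band lobe at an unrelated frequency by
  `dominance` (default 2);
- lobes at harmonics of the dominant peak (within `(k/2 + 1/2)` bins of
  `k·f₀`, the worst-case half-bin scalloping of fundamental and harmonic)
  are excluded from the dominance comparison: a pulse-like wave carries
  intrinsic harmonics that are the same periodicity, not a second one.

The band default is 10–100 s, with a 5–100 s preset for fast components;
both are exposed in configuration. Classification requires a trace at
least twice the band's maximum period; the pipeline clamps the band's
upper edge to half the recording duration (recorded in the manifest) so
short acquisitions remain analyzable.

Thresholds were calibrated by Monte Carlo at the conditions the package
simulates (300 s traces, 1 s sampling): at the defaults, white-noise
false-positive rate is ≤ 5%, and sensitivity on SNR-5 pulse trains and
sinusoids with periods 15–80 s is ≥ 95% (the operating-characteristics
test re-runs this calibration). Known trade-off of the harmonic exclusion:
a genuine mixture of two periodicities at an exact harmonic ratio (e.g.
30 s + 60 s) is indistinguishable from a non-sinusoidal 60 s wave at this
spectral resolution and will be called oscillatory; mixtures at unrelated
periods are rejected.

## Peaks, IPIs, amplitudes

A peak is a sample strictly greater than every other sample within
±`half_window` seconds (default 10 s, converted to ⌈w/Δt⌉ samples;
windows truncate at the trace ends). Strict inequality means plateau ties
yield no peak, making the rule deterministic. The implementation is
verified against a brute-force O(n·w) double-loop scan on randomized
traces, including tie-rich integer-valued ones.

Interpeak intervals are successive peak-time differences; their mean
estimates the period. Amplitude statistics are the relative-intensity
values at peak indices. SDs use the sample convention (ddof = 1; reported
as 0 for a single interval). Both per-trace arrays and their summaries are
emitted so cohort statistics can pool peaks or average within cells first.

## Cross-correlation lag and cycle alignment

Two synchronized traces are truncated to common support, linearly
detrended and z-scored; the normalized cross-correlation is evaluated at
every integer-frame lag within ±`max_lag`. **Sign convention (fixed across
the package): positive lag = the first channel precedes the second.** The
default `max_lag` in the pipeline is half the reference channel's dominant
period, which prevents period-aliased lags.

Sub-frame refinement fits a least-squares parabola to the ±3 frames around
the argmax and reports its vertex. The wave correlation peak is broad
(period ≫ frame interval), so the wider fit averages measurement noise
that a 3-point interpolation would follow; on SNR-5 sinusoidal pairs this
brings the mean absolute error to ~0.3 frames. The reported correlation is
the measured value at the nearest integer lag, not an interpolated one.
Per-cell lag is the whole-trace cross-correlation; cohort summaries report
mean, SD, SEM and n (the ± values in the literature are sometimes SD,
sometimes SEM, so both are available).

Cycle-aligned profiles average fixed-length windows of both channels
centered on each reference-channel peak that has full support; mean and SD
per grid point are returned. The follower's profile maximum falls at
approximately +lag on the relative-time axis, consistent with the
cross-correlation sign, and this consistency is asserted in tests.

## Autocorrelation and wavelet periodogram

The ACF is the biased normalized autocorrelation of the detrended trace
(ACF(0) = 1); the period estimate is the lag of the first side maximum.

The wavelet periodogram uses the analytic Morlet wavelet with center
frequency ω₀ = 6, computed by FFT-domain convolution in the standard
Torrence–Compo normalization (no wavelet package is required). With
ω₀ = 6 the Fourier period is 1.033 × scale. Scales are log-spaced over the
requested period range (60 by default). The ridge is the period of maximum
power per time column; columns whose ridge period exceeds the
cone-of-influence limit (e-folding time √2·s, i.e. period ≤ 1.033/√2 ×
distance to the nearest trace edge) or whose power is zero are masked NaN.
No significance testing against AR(1) nulls is performed.

## Kymographs and image reductions

Reslice samples the stack along a line segment at 1-px arc-length spacing
with bilinear interpolation, averaged across an odd number of
perpendicular offsets (the ImageJ tool's exact kernel is unspecified;
bilinear is smooth and exactly linear, which the tests exploit). A
traveling wave appears as bands whose slope is 1/speed (s/μm). The band
slope estimator cross-correlates adjacent kymograph rows with sub-frame
parabolic refinement — inter-row delays are usually a fraction of a frame —
accumulates the delays along the line, and fits distance vs. delay by least
squares; on noiseless simulated planar waves it recovers the speed to
~0.1%.

The 10-frame rolling average is trailing (causal), keeping event onsets
aligned; it, background subtraction and montage/maximum-projection are
display aids and are never applied before quantification unless explicitly
configured.

## The simulator: what it emulates, what it does not

Channel intensity is

```
I_c(x, t) = bg_c + B_c(t) · mask(x) · [base_c + amp_c · g(φ(x,t) − 2π·lag_c/P)] · m_c(x)
```

with phase field `φ(x, t) = 2π(t/P − d(x)/(vP))`, `d` the planar (+x) or
radial propagation coordinate in μm, `v` the wave speed, and
`B_c(t) = exp(−k_bleach·t)` applied to the signal only (the background is a
camera offset and does not bleach). `g` is a raised-cosine pulse peaking
at phase 0 with unit height and zero minimum — so `base` is exactly the
trough level and `base + amp` the peak — with duty cycle 0.5 (a half-cycle
rise-and-decay, matching the pulse-like appearance of real waves); a
sinusoid (also scaled to [0, 1]) is retained for closed-form tests. Noise
is Poisson shot noise at a configurable gain followed by additive Gaussian
read noise; all randomness flows from one seeded generator per call and
identical (config, seed) pairs are bit-identical.

Diffuse channels have morphology factor 1 inside the elliptical cell mask.
Puncta channels are sums of fixed Gaussian spots at loci drawn uniformly
inside the mask (kept off the rim); each punctum blinks coherently with
the wave phase *at its own center*, so its intensity argmax is stationary
by construction — modeling structures that appear and disappear in place
rather than move. The mask must lie strictly inside the frame so an
off-cell background region always exists.

Defaults describe the stated acquisition world: 0.6 s frame interval
(0.6–4 s supported), 0.11 μm/px, 25 s period (valid band 5–100 s),
per-channel lags of a few seconds (|lag| < P/2 required for
identifiability), SNR ≈ amplitude/noise on the order of 5–20. No
quantitative wave speed is established for this system; the 0.3 μm/s
default is a placeholder on the scale of one cell diameter per couple of
periods and is flagged as such.

Not modeled: any reaction–diffusion or mechanochemical wave mechanism,
membrane fluctuation artifacts (TIRF-depth optics), cell-shape change,
drift, or spatially varying background. A green test against the simulator
therefore establishes that the *measurement* chain is correct for
wave-like signals with the stated noise model — not that the biological
interpretation of any particular recording is correct, nor that the
pipeline is robust to optical artifacts it does not simulate.

## Degenerate inputs and numerical guards

- Exactly constant traces: linear detrending leaves ~1e−15 float residue;
  a relative flatness guard (SD ≤ 1e−10 of the value scale) makes the
  classifier return a negative call, the wavelet map empty, and
  cross-correlation raise, instead of amplifying rounding noise.
- Plateau ties never produce peaks; empty peak sets propagate as NaN
  statistics rather than errors.
- CSV outputs are written with a fixed float format (`%.10g`), making
  identical (config, seed) runs byte-identical.
- Frame interval and pixel size are mandatory metadata: a TIFF without
  them is rejected with an explicit error rather than assuming 1 s.

## Known limitations

- Lags are estimated from whole-trace cross-correlation; slowly drifting
  phase relationships within a recording are averaged, not tracked
  (per-cycle lags can be obtained by running `crosscorr_lag` on windows).
- The classifier's harmonic exclusion cannot distinguish a true 2:1
  mixture of periodicities from one non-sinusoidal oscillation.
- The kymograph speed estimator assumes a single dominant propagation
  direction along the resliced line.
- A puncta channel samples the wave phase at its (random) loci, so an ROI
  trace over puncta carries a phase offset of up to ROI-width/wave-speed
  relative to a diffuse channel in the same ROI — apparent lags between a
  diffuse and a puncta reporter include this spatial-sampling term, in
  simulation as in real recordings. Lag-recovery validation therefore uses
  matched morphologies.
- No cell segmentation: the cell mask comes from configuration or the
  simulator; off-cell background ROIs are the user's responsibility on
  real data (overlap with a declared mask only warns).
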