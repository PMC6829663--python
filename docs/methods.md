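# Methods

This note documents the models, parameter choices and numerical
decisions behind `tirfgran`, and what the synthetic benchmarks do and do
not establish about real recordings.

## Image formation model

Rendered movies assume a diffraction-limited microscope with a Gaussian
PSF (sigma 1.3 px at 100 nm/px, i.e. ~130 nm, appropriate for a
high-NA TIRF objective) and an EMCCD-like camera:

    expected photons = background + Σ_spots amplitude · G(x, y; σ_psf)
    pixel value      = clip(round(Poisson(expected) + N(0, σ_read)), 0, 65535)

quantised to 16 bits.  This is the minimal model with the two noise
features the analysis has to survive — shot noise scaling with
intensity, and additive read noise — and deliberately omits EMCCD
gain-register excess noise, evanescent-field depth decay, drift and
photobleaching.  Signal-to-noise is parameterised as
`amplitude / sqrt(background + σ_read²)`, the peak height in units of
the background noise sd.

## Granule kinetics in the simulator

Granules arrive as a Poisson process (or as an exact count at uniform
random frames when a benchmark prescribes one).  Each arrival is
long-lived ("docked", residence uniform 45–120 s by default, so always
beyond the 40-s survival horizon) with probability `p_dock`, otherwise
a short-lived "visitor" (uniform 2–20 s); an optional "transit"
population moves ballistically at 2 px/frame instead of being confined.
Confined granules jitter around their arrival point with per-frame
Gaussian displacements of sd 0.3 px (30 nm), which makes the
confinement classifier discriminative without being trivial.
Appearance is rendered as a 2-frame intensity ramp, emulating axial
approach into the evanescent field.  Departure is abrupt by default:
an explicit departure-ramp option exists, but the default keeps
ground-truth frame ranges exactly recoverable by the tracker, and no
benchmark mixes spontaneous departures into movies scored for fusion.

Fusion movies place docked granules at a minimum separation of 10 px
(1 µm).  This reflects how sparse docked, fusion-competent granules
are — of the ~10,000 granules in a beta cell fewer than 100 are docked,
several micrometres apart on the footprint — and keeps neighbouring
PSFs from sharing saddles at low SNR, where a prominence criterion
(like any human scorer) starts to lose closely spaced spots.  Loss is
completed within 1 frame (gone between consecutive frames) or 2 frames
(one intermediate frame at half amplitude).

What the simulator does **not** emulate: bleaching, stage drift,
axial intensity fluctuations of docked granules, kiss-and-run events,
vesicle clusters, or inhomogeneous backgrounds.  Green test suites
therefore demonstrate correctness of the measurement chain under the
stated statistical model, not robustness to every artefact of real
movies.

## Spot detection

Frames are smoothed with a Gaussian matched to the PSF; candidate
maxima are those surviving h-maxima suppression with h equal to the
prominence threshold (default: 5 × the MAD-based sd of the smoothed
frame — the "noise tolerance" of an ImageJ-style find-maxima).  Pure
prominence always leaves one maximum per frame on an empty noise field
(the global maximum survives any h), so detections must additionally
rise above the frame median by h.  Of two maxima closer than
`min_separation` (default 3 px) the brighter wins.  Coordinates are
refined by a 3×3 centre of mass on the smoothed image, good to ~0.1 px
at the benchmark SNRs, which matters because confinement is judged at a
1.5-px radius against 0.3-px jitter.  Detection is invariant to affine
intensity rescaling when the prominence is rescaled identically.

## Tracking and docking classification

Linking is greedy closest-pair-first, gated at 4 px, bridging up to 1
dropped frame; granule densities at the footprint are low enough that
globally optimal assignment would add complexity without changing the
result.  Classification applies the dwell-time rules (approach ≥ 2 s
confined; docked ≥ 25 s, ties dock; visitor otherwise; transit if
confinement fails).  The confinement radius (1.5 px = 150 nm) is not
fixed by the qualitative "laterally confined" criterion and remains
explicit configuration echoed into all outputs.  The stable-docking
fraction counts only tracks that appear after frame 0 (the standing
pre-docked pool is excluded from approach counts but not from density)
and, when the movie length is known, excludes approaches too close to
the end for the 40-s survival window to be observable — censoring them
rather than scoring them as failures removes an edge bias.

## Fusion detection

An event requires, relative to the mean of the five preceding
detections (background-corrected): a final value below 50%, a loss of
at least 50% within ≤ 2 frames from the last stable sample, a
post-window (5 frames) mean below 50% with no sample returning above
70%, and no other detection within 2 px during the post window.  The
drop-magnitude requirement is what separates abrupt loss from gradual
dimming: a ramp eventually falls below half the rolling pre-level but
never loses half of it in two frames.  When the movie is available the
post-event level is sampled from the smoothed movie at the last
position, on the same intensity scale as the tracker's peak values;
without it, a frame inside the known movie length with no nearby
detection counts as zero, and frames beyond everything observable are
treated as unknown, so a track that merely ends with the recording is
not an event.  Events within 2 frames of the movie end are discarded
(incomplete post window).  All thresholds are configuration with the
stated defaults; the underlying criterion is qualitative and these are
the package's operationalisation.

## Enrichment statistic

Each profile sample is treated as a unit-length cell centred on it, so
a region of n samples has width n and a uniform profile of value c
integrates to n·c.  This convention is what makes the statistic exactly
consistent with its null N_gr/N_All.  The default "trapezoid" rule
integrates the piecewise-linear interpolant over the cell span
(half-sample end caps, constant extension at profile ends); the
"rectangle" rule sums samples directly and reproduces hand-worked
examples exactly.  With either rule E is bounded in [0, 1] (the
numerator is a sub-integral of the non-negative profile-minus-min) and
invariant under affine intensity maps a·p + b, a > 0.  N_gr comes from
the marker channel (FWHM above the profile minimum, crossings by linear
interpolation) and is applied to the probe channel's profile.  A
profile with no signal above its minimum makes the statistic 0/0; the
guard ε = 10⁻⁶ · N_All · max(profile) flags such results rather than
computing them.  Because only E, the excess E − N_gr/N_All and the
peak/min ratio are all plausible summaries, the result object reports
all three.  Condition-level statistics are means over per-cell values
± SEM.

## Traces and fitting

F/F0 uses the mean of the background-corrected pre-stimulus window; the
window must precede stimulus onset and its F/F0 mean is 1 by
construction.  The maximal response applies a 3-point median filter
first so a single-frame event under the footprint cannot dominate a
per-cell statistic.  Exponential fits initialise from a log-linear
regression (offset seeded slightly below the trace minimum) and refine
by Levenberg–Marquardt with tight tolerances (1e-13), which recovers
noiseless time constants to ~1e-9 relative without user-supplied
starting values; constant traces, fewer than 5 samples, non-convergence
and non-positive fitted τ are flagged as errors.

## Statistics layer

Two-tailed paired/unpaired t tests and OLS trends delegate to scipy;
two-way ANOVA (type-II) and Tukey HSD delegate to statsmodels and are
validated against a directly computed 2×2 balanced example — no bespoke
implementation is claimed.  Percent change is (mean_a − mean_b)/mean_a
× 100 with first-order error propagation.  Degenerate inputs are given
their limits: identical groups → t = 0, p = 1; perfectly consistent
nonzero paired differences → t = ±∞, p = 0; zero variance in both
unpaired groups with different means is an error.

## Benchmark problem sizes

The parameter-recovery benchmarks use 200 simulated approaches on a
256×256 field over 400 frames at SNR 10 for docking (binomial 95% CI
±6.9 percentage points at n = 200), movies with 30 and 9 fusion events
at SNR 5 on 200×200 over 120 frames, and 250×250 single frames
(625 µm²) with 100/49/77 spots for density and structure counts.  These
sizes keep a full benchmark run well under a minute per target on one
CPU while leaving the statistical tolerances meaningful; all randomness
derives from one integer seed.

## Known limitations

* No axial (z) information is inferred from intensity; "approach" is
  operationalised purely as appearance.
* Undocking-rate modelling, kiss-and-run discrimination and
  pre-fusion brightening ("flash") detection are out of scope; only the
  loss criterion is implemented.
* The footprint mask default (Otsu on the temporal mean) is a
  convenience; quantitative density comparisons should use matched,
  explicit masks.
* The simulator's frame interval is free configuration; all dwell-time
  thresholds are specified in seconds and converted per movie.
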