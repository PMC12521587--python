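# Methods

`vasotone` is a desk-scale re-implementation of a vasomotor
electrophysiology analysis workflow: multichannel extracellular recordings
from the arterial wall are preprocessed, reduced to rhythm- and
power-based features, discriminated by vasomotor state, cross-checked
against the clinical arterial-stiffness index, and fed into a simulated
closed-loop detection/stimulation controller.  Because no recording
hardware is involved, every stage is driven by a synthetic generator whose
statistical structure matches what the analysis assumes; the generator is
first-class, tested code, and all validation is parameter *recovery*:
generate with known ground truth, analyze, compare.

## The synthetic generator

**Background noise.**  Channels carry independent white Gaussian noise
rescaled post hoc so that each channel's RMS *after the analysis band-pass*
(fourth-order Butterworth, 0.5–50 Hz, forward–backward) equals the
configured floor.  The in-vivo preset is 2.63 μV, the noise level
achievable with a chronically adhered vessel interface.  The in-band RMS is
evaluated spectrally (Parseval, weighting the realization's spectrum by the
filter's squared zero-phase magnitude response), which is equivalent to
time-domain filtering away from record boundaries and much cheaper on long
64-channel records.  We deliberately define "in-band" through the analysis
filter rather than a brick-wall FFT mask: the two differ by about 5% in
equivalent noise bandwidth (the Butterworth edges roll off), and the quoted
in-vivo figure is a post-band-pass measurement.

**Vasomotor oscillation.**  Vasomotor tone fluctuates slowly; the generator
uses a periodic piecewise-linear cycle (valley → peak → valley) at a
default dominant frequency of 1.2 Hz — inside the 0.5–50 Hz analysis band
and below cardiac frequencies; the true dominant band of vasomotor activity
is not pinned down numerically, so this default is a configurable
placeholder, not a claim about real vessels.  One period T is partitioned
into a rise of duration t_r and fall of duration t_f with
t_r + t_f = T and t_r/t_f equal to the configured rise/fall ratio.  State
presets: constriction 0.6 (fast rise, slow fall), dilation 1.6, all
suppressed states 1.0.  `osc_amp` (default 25 μV, i.e. an SNR of ~10
against the in-vivo noise floor, consistent with clearly visible vasomotor
deflections) is half the peak-to-valley excursion.

**Dose scaling.**  Drug dose maps to amplitude through g(d) = 1 + κ·d with
κ = 1 — the simplest strictly increasing law; only monotonicity is asserted
anywhere, never the particular slope.

**Suppression.**  Denervated and stented states multiply the oscillation
amplitude by (1 − s): s = 0.8 denervated, 0.4 acutely stented, 0.6
chronically stented, 0.1 post-stimulation.  Only the ordering (denervated
most suppressed, chronic worse than acute, post-stimulation nearly
recovered) is meaningful.

**Propagating wave / CAR survival.**  Every channel sees the same cycle
advanced in phase along the electrode grid's axial (row) direction, by
default one full cycle across the 8 rows.  This models a vasomotor wave
travelling along the vessel and has an important analytical consequence:
if the oscillation were perfectly common across channels, the common
average reference would annihilate it.  With the phase gradient the
cross-channel mean is nearly zero and CAR removes only common-mode noise.
Note that single-row layouts (e.g. an 8-channel strip) share one phase, so
CAR on such arrays does cancel the oscillation — use `apply_car=False`
there.

**Hemodynamics.**  The arterial diameter waveform is a raised-cosine pulse
between the preset diastolic (Dd) and systolic (Ds) diameters at the preset
heart rate (default 220 beats/min, an anesthetized-rabbit rate), starting
mid-rise so that a trace of k cardiac cycles contains k interior systolic
peaks and k interior diastolic valleys.  Cuff pressures ride along as
scalars.  What the generator does **not** emulate: dicrotic notches,
respiratory modulation, beat-to-beat pressure variability, probe-contact
artifacts — so passing tests show the *analysis* is correct, not that it is
robust to every artifact of real ultrasound tracking.

## Preprocessing

Stage order: corrupted-channel masking (flat below 0.1 μV peak-to-peak, or
above the 5 mV recorder range for >1% of samples) → IIR notch at the mains
fundamental (50 Hz default, the local mains frequency) and its first
harmonic, Q = 30 → common average reference over unmasked channels →
fourth-order Butterworth band-pass, 0.5–50 Hz → 100-ms sliding RMS with
50% hop.  All filters run forward–backward: cycle morphology (t_r/t_f)
must not be skewed by phase delay; the effective order doubles.  Filters
are implemented as second-order sections (the 0.5 Hz edge at 4 kHz is
numerically hostile in transfer-function form), and the pad length is
extended to ~3 periods of the low cut-off (~5 ring-down constants for the
notch) — the library defaults are far too short for these bands.

**Boundary ringing.**  Zero-phase filtering of a finite record excites the
lightly damped 0.5 Hz edge at both boundaries; this ringing is an artifact
of the finite record, not signal, has large per-channel variance, and
decays with a ~0.8 s time constant.  Steady-state RMS measurements
(`channel_rms(..., edge_guard=...)`) therefore exclude a 6-s guard
(three periods of the low cut-off) at each end.  With the guard, the
measured post-chain noise floor is 2.63 μV times √(63/64) (the CAR
variance factor for 64 independent channels) less ~1% removed by the
notch ≈ 2.58 μV.

## Features

**Cycle segmentation.**  Peaks and valleys are located by prominence- and
separation-constrained peak picking (defaults: prominence 2× the unscaled
median absolute deviation — large enough to reject noise wiggles, small
enough to keep pure tones, whose peak prominence is only ~2.8× MAD;
separation a quarter of the dominant spectral period).  Extremum *times*
are then refined to sub-sample precision by intersecting straight lines
fitted to the two flanks: exact for piecewise-linear cycles, unbiased in
time for symmetric smooth peaks, and far less noise-biased than the raw
argmax, which drifts toward the shallower flank.  Cycle amplitude is the
peak value minus the mean of the two flanking valley values (robust to
slow drift).  Boundary extrema have reduced prominence (their outer base is
the record edge) and may drop out, so an n-cycle record yields n−1 or n
triplets.

**Windowed band power.**  Per 100-ms Hann-tapered window, the one-sided
periodogram PSD is integrated over positive-frequency bins up to 50 Hz and
averaged across windows (50% overlap).  A 100-ms window has 10-Hz bin
spacing, so the 0.5 Hz band edge is unresolvable at that length; the
windowed statistic therefore integrates all bins in (0, 50] Hz, and a
longer window (2 s) is available for frequency-resolved spectra.  Two
estimator caveats, both inherent and deliberate: (i) a slow oscillation is
nearly constant within 100 ms, so most of its energy appears in the
excluded DC bin — absolute windowed power under-reports slow components,
but *ratios* (relative power) are unaffected because the captured fraction
cancels; (ii) a tone exactly one bin above DC loses 1/6 of its Hann-tapered
power into the DC bin, so Parseval checks should use tones at least two
bins from DC.

**Relative statistics.**  Relative power and relative amplitude are
post/pre ratios within one subject (same channel, before vs after an
intervention); amplitude uses the mean cycle amplitude, falling back to
peak-to-peak when no cycles are found.  Both are dimensionless and
scale-invariant.

## State space

Per-channel feature vectors (rhythm ratio mean/SD, RMS, peak-to-peak,
zero-crossing rate, band power, spectral centroid) are averaged across
channels per segment, z-scored per dimension (constant dimensions dropped
with a warning; missing rhythm entries imputed with the column mean), and
embedded by PCA-initialized t-SNE (perplexity 10 — a small-n default; the
description of the original analysis is ambiguous between t-SNE and a PCA
view, so `method="pca"` switches to the first two principal components).
Separation quality is the silhouette score of the embedded points against
ground-truth state labels.  Embeddings are seed-dependent and never
compared coordinate-wise across seeds — only through the score.

Two simulation studies are built in.  The **separability study** asks
whether baseline/constriction/dilation segments (20 each, 5 s, in-vivo
noise, 16 channels) separate at all; scores are ~0.9.  The **resolution
study** compares 64 against 8 axially subsampled channels on a shared
feature table.  Channel count acts through spatial averaging of
per-channel feature noise, so this study runs in a weak-signal regime
(oscillation amplitude 5 μV, about twice the noise floor — subtle
vasomotor activity rather than a strong evoked response); with a strong
signal every channel count separates the states and the comparison
saturates.  Study segments are generated mains-free (the states, not the
notch stage, are under study) at 250 Hz, which carries the full analysis
band at a fraction of the cost.

## Arterial stiffness

β = ln(Ps/Pd) / ((Ds − Dd)/Dd), with Ds/Dd the per-cycle systolic maximum
and diastolic minimum of the diameter waveform.  The natural logarithm is
used.  Ds and Dd are averaged over at least three cycles *before* β is
evaluated (the clinical caliper procedure); per-cycle β values are
reported for spread.  β is dimensionless, invariant to diameter units,
decreasing in pulse strain at fixed pressures and increasing in the
pressure ratio at fixed strain; higher β means a stiffer artery.  Two
documented presets encode the stent experiment: post-stent
(Ps/Pd = 110/85 mmHg, Dd = 3.000 mm, Ds = 3.0411 mm, β ≈ 18.83) and
post-stimulation (Ds = 3.0550 mm, β ≈ 14.06); the diameters were obtained
by inverting the stiffness relation at those β values and round-trip to
<0.5% through the full extraction path.

## Closed loop

The controller watches the distal monitor channel's in-band power per
5-s control window (a sinusoidal carrier at the latent power plus
calibrated noise; mean-square of the band-passed window).  Dysfunction is
declared when power falls strictly below θ = 0.5 of the healthy reference;
that starts a treatment episode in which every still-deficient window
(below the recovery band) triggers one charge-balanced biphasic pulse train
— so each stimulation is preceded, within its window, by a detection.
Trains are cathodal-first, 100 μs per phase, 300 μA default (30 nC per
phase, zero net charge), 50 pulses at 50 Hz (repetition rate and train
length are placeholders; no value is asserted on them).  Safety: >500 μA is
hard-rejected (arrhythmogenic), (300, 500] μA requires an explicit
override.

Each train updates the latent power by P′ = P + γ·(ref − P), with
γ(100 μA) = 0.15 and γ(300 μA) = 0.55 — a *calibration*, chosen so the
noiseless trajectory from a chronically stented start (40% of healthy
power) reads 0.40 → 0.73 → 0.8785 of reference: a significant deficit
recovering into the healthy band after exactly two stimulations, matching
the staged recovery pattern the system is meant to reproduce.  The
recovery band is 0.85 of reference with a 2-window hold (0.8785 sits inside
it; a 0.9 band would require a third train under the same γ).  Detection
threshold and recovery band are invented, logged configuration, not
measurements.  The closed-loop presets are power fractions of the healthy
reference (chronic stent 0.4, acute 0.6, denervated 0.2) — a power-domain
convention, distinct from the generator's amplitude-domain suppression.
Recovery is held indefinitely; the persistence of the modulation effect is
not modelled mechanistically.

## Numerical and design notes

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration + seed reproduces
  identical arrays and byte-identical serialized session logs.
* Time is seconds from record start; channels are rows; grid coordinates
  are (row, col) on the 8×8 layout, row-major, 0-based.
* Containers: delimited text (μV at 1e-6 precision, JSON sidecar for rate,
  mask, grid and metadata) and HDF5 for large simulations.  Requests for
  other container formats raise a clear error naming the supported ones.
* Validation problem sizes: noise-floor study 20 seeds × 120 s × 64
  channels at 4 kHz; rhythm and dose studies 20 seeds × 30 s single-channel
  at 1 kHz; separability 20 seeds, resolution 9 seeds at 250 Hz; safety
  fuzz 100 sessions.  Chosen so the full validation run completes in
  minutes on one CPU.

## Known limitations

* The generator is phenomenological: no membrane/ion-channel model of
  smooth muscle, no hemodynamic feedback between stiffness and
  electrophysiology beyond paired presets, no simulation of imaging.
* The exact feature list used for state discrimination in vivo is not
  enumerable from published descriptions; the vector here is a reasonable
  composition of the named components, and the separability score is an
  unsupervised stand-in for visual cluster separation.
* Absolute windowed band power under-reports sub-window-rate oscillations
  (see above); all pipeline conclusions rest on ratios or comparisons where
  this cancels.
* Single-row arrays lose the common oscillation under CAR (no axial phase
  diversity); the pipeline exposes `apply_car=False` for that geometry.
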