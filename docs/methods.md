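# Methods

This note documents the models, conventions, and numerical choices behind
`polarspike`, and what the synthetic-data generator does and does not
emulate.

## Waveform categorization

Snippets are 32 samples (1.6 ms) at 20 kHz with the detection extremum at
0-based sample 15.  Categorization operates on the per-electrode mean
waveform: the mean of the first 3 samples (0.15 ms) is subtracted, then
mean and SD are upsampled four-fold in time by cubic spline to two
128-sample vectors (80 kHz effective rate; spline undershoot of the SD is
clipped at zero).  All local extrema of the upsampled mean are detected;
the largest local maximum is the peak *p*, the smallest local minimum the
trough *n*, and BPI = (p − |n|)/(p + |n|).

Conventions where a rule had to be fixed:

* **Endpoints count as local extrema.**  In a 1.6 ms window a monotone
  edge would otherwise have no candidate, so *p* and *n* coincide with the
  global extrema of the vector.
* **BPI clamp.**  When every local extremum shares one sign (possible
  after baseline subtraction of an all-negative or all-positive trace) the
  raw ratio can leave [−1, 1] by a sliver; the value is clamped so the
  documented range holds for any input.
* **SD thresholds use the upsampled SD vector** at the extremum sample,
  consistent with the two-128-sample-vector representation.  With an
  all-zero SD (noiseless input) the comparisons reduce to `extremum > 0`
  and categorization is by shape alone; this is intended and documented in
  the API.
* Decision rules (default preset): B if the peak precedes the trough, the
  peak exceeds 1.25 SD, the |trough| exceeds 1 SD, and −0.6 < BPI < 0.8;
  otherwise P if p > |n| and p > 1.75 SD; otherwise N if |n| > p and
  |n| > 1.75 SD; otherwise uncategorized.  The alternate preset uses the
  symmetric 1/1 SD rule for B and 2 SD for P/N.  Both live in one
  `CategoryThresholds` config object.

**Spike width** is the inverse of the dominant frequency of the upsampled
waveform's magnitude spectrum, zero-padded to 16384 samples (≤ 5 Hz grid at
80 kHz) and searched over 100–3000 Hz with DC excluded.  **Spatial span**
is the longest vertically contiguous run of categorized electrodes times
the site spacing; a single categorized electrode counts as one spacing.
**Main-channel ties** break to the lowest channel id.

Cell typing of N-units uses a two-component Gaussian mixture on
(trough-to-peak time, spike width) of the main channel; the narrower
component is INT.  The classifier is pluggable (any object with
`fit`/`predict_proba`); when the two fitted components are not separated
the units are split by a 0.4 ms trough-to-peak threshold with a warning.
Non-negative units are never entered into the mixture.

## Extremum timing

Lags are measured between extrema of upsampled *mean* waveforms (unit
level, not per spike), hence quantized to 12.5 µs.  For multi-N MM units
the reference is the largest-magnitude N channel (a proxy for the soma).
Signed distances are y(non-negative channel) − y(N channel) with larger y
toward the brain surface; cross-shank pairs are flagged and excluded from
distance analyses.  Median confidence limits use the distribution-free
binomial order-statistic interval (the paper-style figures leave the CI
method open; this is our convention), with a seeded 10⁴-resample bootstrap
fallback below n = 6 where no valid order-statistic pair exists at 95%.

## Monosynaptic connectivity

Count CCHs use 0.1 ms bins over ±50 ms with bin edges symmetric around
zero, so the causal monosynaptic region of interest (0, 5] ms is exactly
50 bins.  The baseline is a hollowed running median of the count CCH
(window 10 ms, evaluated bin ± 5 bins excluded; edges shrink the window).

The deconvolution step removes presynaptic burst structure.  The kernel
lives on integer bin shifts: 1 at zero shift, and for each nonzero shift
the ACH interpolated at that lag, minus the mean off-centre level, per
reference spike.  The mean subtraction gives the kernel exactly unit DC
gain, so total count mass is conserved and a flat (Poisson) ACH yields the
identity; only deviations from flatness (bursts) are deconvolved.
Division is Tikhonov-regularized in the Fourier domain with
ε = 10⁻³ × max kernel power, and a `mode="off"` bypass is exposed.  The
convolutional model assumes every reference spike transmits with the same
probability; when only burst-onset spikes transmit, echo suppression is
partial by construction.

STG integrates the transmission curve (deconvolved CCH − baseline, scaled
to spikes/s by n_ref and the bin width) from the ROI extremum outward to
the nearest zero crossings, never across t = 0.  Detection is a per-bin
Poisson tail test of the deconvolved counts against the baseline,
Bonferroni-corrected over the 50 ROI bins at α = 0.001, requiring at least
two adjacent significant bins of one sign ("consistent" peak/trough);
zero-baseline bins are tested against a floor of 0.1 counts.  The
inhibitory ROI mirrors the excitatory one.  Session-level vINT→BIP
fractions use an exact one-tailed Binomial test against chance = α.

## Ripples

The band-pass kernel is the difference of two Gaussian low-pass FIR
kernels whose −3 dB points sit at 80 and 250 Hz, truncated at 8 σ of the
wider Gaussian (odd length), and normalized to unit gain at the passband
peak (the raw difference tops out near 0.69).  The kernel is symmetric and
applied as zero-lag convolution.  The envelope is |filtered| low-passed at
55 Hz (a conventional choice, exposed in config); baseline mean/SD come
from a copy clipped at 5 SD over the non-theta immobility mask (whole
signal with a warning if the mask is empty).  Events: unclipped envelope
> 5 SD, edges extended to 2 SD, merged if overlapping, 15–400 ms duration
bounds (convention), aligned to the band-passed trough nearest the power
peak.  Layer centre per shank = channel with maximal mean in-event
envelope, ties to the lowest channel id.  Phase convention: 0 at the
filtered signal's peak, π at the trough, increasing with time (Hilbert
analytic phase).  Rate gain = in-event rate / immobility baseline rate
with an upper-tail Poisson test; phase locking reports the circular mean,
resultant length R, Rayleigh p, and a 20-bin phase histogram, flagged when
fewer than 10 in-event spikes are available.

## Place coding

150 cm track, 60 × 2.5 cm bins, trials split by running direction, trials
with mean speed < 10 cm/s dropped.  Active: ≥ 5 spikes in some bin pooled
over trials.  Stable: Spearman correlations of all same-direction
trial-pair maps, each against a null of circular shifts of one trial's map
(the shift preserves the map's autocorrelation; 200 shuffles, plus-one
correction), combined as the geometric mean over all pairs in both
directions and compared to 0.05.  Note that a geometric mean of many
uniform p-values concentrates near e⁻¹, so with many trial pairs this
criterion is conservative (its null rejection rate is far below α); the
suite therefore checks it as a one-sided bound.

Field detection is recursive: the chance rate is the pooled rate outside
already-accepted fields; a field seeds at the most significant bin whose
pooled count exceeds the Poisson upper tail at Bonferroni-corrected 0.05
given chance × occupancy, extends over contiguous bins whose rate exceeds
the chance rate, is removed, and the search repeats; fields with < 30
spikes are discarded.  Spatial information is the Skaggs rate form
I = Σᵢ pᵢ λᵢ log₂(λᵢ/λ̄) in bits/s; in-field gain is the occupancy-weighted
in/out rate ratio, capped and flagged when the out-of-field rate is zero.

Phase precession maximizes the mean resultant of (phase − 2π·slope·x) over
a slope grid (±0.1 cycles/cm, 10⁻³ steps) with bounded local refinement;
goodness is the resultant at the optimum and the onset phase is the
circular mean of the slope-corrected phases at the field start.  The
effect size divides the observed goodness by the median of 300 fits to
permuted phase–position pairs.  Two flags are returned: `significant`
(goodness above the permutation 95th percentile — the quantity whose null
rate calibrates at ~0.05) and `precessing` (significant *and* negative
slope, the physiologically signed criterion, whose null rate is
correspondingly about half of α).

## Statistics

Rayleigh's test uses Z = nR̄² with the standard finite-n series
correction.  The Wheeler–Watson two-sample test uses uniform scores
(circular ranks, average ranks on ties) with the χ²(2) approximation, and
a label-permutation null when either sample has fewer than 10 angles.  The
G-test is 2 Σ O ln(O/E) with zero-observation cells contributing zero and
a Bonferroni helper for families of comparisons.  All permutation
p-values carry the plus-one correction and lie in (0, 1].  Wilcoxon,
Mann–Whitney, Kruskal–Wallis, Binomial, Poisson tails, and Spearman are
delegated to scipy behind thin adapters.

## Synthetic data: what it emulates, and what it does not

Templates are sums of Gaussian lobes, so the continuous waveform is
analytic and its ground-truth extrema are read off a dense 1 µs grid of
the closed form, independently of the 20 kHz sampling and of the spline
pipeline under test.  The N archetype is a trough with a dominant rebound
after it and a slightly smaller dip-side lobe before it; the P archetype
is its mirror image.  The near-symmetric flanks (0.3/0.25 of the main
lobe, ±2 σ) serve three purposes: they fix the lobe order so the B rule
cannot fire on N/P shapes regardless of noise, they almost cancel the
overlap-induced shift of the main extremum (residual ~0.03 σ, a few µs,
and recorded exactly in the manifest), and they move the spectral peak off
DC so the dominant-frequency width scales as 1/σ.  B templates are a
positive peak 3 σ before a larger trough (peak/trough 0.6–0.9, BPI about
−0.25…−0.05).  Amplitudes span 40–200 µV and lobe σ 0.05–0.11 ms by
default; MM units put the N template on the main channel and a half-
amplitude P or B template 1–2 sites away with a configurable lag of tens
of µs.

Spike trains are homogeneous Poisson thinned by a 2 ms dead time.
Excitatory coupling adds a postsynaptic spike per presynaptic spike with
the stated probability at lag + Gaussian jitter; inhibitory coupling
deletes postsynaptic spikes in a (lag, lag + 3 ms] window with the stated
probability (any mechanism producing a CCH trough suffices for the tests).
Realized added/deleted counts are recorded for calibration.  Recordings
add i.i.d. Gaussian noise per sample.  LFP is 1/f-amplitude noise plus a
theta sinusoid and Gaussian-windowed ripple bursts whose amplitude is
`snr` × the in-band background SD on the centre channel and decays
exponentially with vertical distance (length constant 60 µm); event
centres are Poisson, thinned to a 2-duration minimum separation.  Track
sessions are constant-speed back-and-forth runs with Gaussian spatial
tuning (thinning of a homogeneous process), and in-field spike phases
follow the linear precession model plus von Mises noise (κ = 4); phases
are generated directly rather than read from a simulated theta LFP.

The generator does **not** emulate: biophysical compartments, electrode
impedance or spatially correlated noise, spike-sorting errors or overlap
artefacts, theta-modulated running speed, or ripple–spike interactions.
Passing the recovery suite therefore demonstrates correctness of the
analysis chain under its stated model, not robustness to every failure
mode of real recordings.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own desk-scale study conditions: 200 units for
categorization recovery (200 spikes/unit at noise SD = amplitude/10);
30-unit MM populations for lag medians; 10⁴ presynaptic spikes (10 Hz ×
1000 s) per STG point and 2000 independent 120 s pairs for the null
calibration; 10 min of 8-channel LFP at 1250 Hz with ~20 events/min at
SNR 10; 80-trial track sessions for recovery and 200 slope-0 fields (40
trials) for the precession null; 400–1000 replicates for the type-I error
checks.

## Known limitations

* The deconvolution kernel is estimated from the empirical ACH; for
  trains whose transmission depends on intra-burst position the
  convolutional model is only approximate (see above).
* The recursive field detector assumes pooled-count Poisson statistics;
  strong trial-to-trial rate modulation inflates its seed rate.
* Order-statistic median CIs are conservative at small n; bootstrap
  fallback CIs below n = 6 have no exact coverage guarantee.
* The Gaussian-mixture cell typer is a generic stand-in with a pluggable
  interface; its default features (trough-to-peak, spectral width) are
  deliberately simple.
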