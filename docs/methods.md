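# Methods

This note documents the models, algorithmic interpretations and numerical
choices behind voltscope, in the spirit of a methods appendix: what each
stage assumes, which knobs matter, what the synthetic generators do and do
not emulate, and where the design was genuinely open.

## Signal primitives

**Zero-phase filtering.** All quantitative filtering is forward–backward
(`filtfilt`/`sosfiltfilt`) so features keep their timing: Butterworth for
band definitions stated as frequency corners (0.1–50 Hz subthreshold band,
40 Hz spike high-pass, 12 Hz trialization low-pass), Bessel (order 4) for
the 130–200 Hz ripple band where waveform shape matters, and Hamming-window
FIR for the pupil-phase filters (5 Hz low-pass, 2–10 Hz band-pass, 0.1–1 Hz
amplitude band). FIR tap counts default to four periods of the lowest band
frequency, capped at a third of the trace, balancing transition width
against edge transients. NaN gaps are linearly interpolated before filtering
and re-masked after; an all-NaN trace is an error. Zero-phase IIR filtering
commutes with time reversal only up to edge transients; tests therefore
compare interiors.

**Exponential fits.** Step-response kinetics use
F(t) = c + k·e^{(t−t0)λ} (+ k₂·e^{(t−t0)λ₂}) for t > t0 and the plateau
c + k (+ k₂) before the onset, with the onset t0 fitted jointly. The RSS
surface is very sharp in t0 (the model's derivative is discontinuous there),
so the fit scans a deterministic grid: 11 coarse onsets plus a
derivative-based onset estimate, each combined with 8 log-spaced time
constants (pairs for the dual model) whose amplitudes are solved linearly;
the onset grid is then zoomed (×5 per level) down to two-sample resolution
before a single Levenberg–Marquardt polish of all parameters. The procedure
has no random element. For the dual model the faster component is listed
first and the fast fraction is k/(k+k₂); a second component below 10⁻⁶ of
the first collapses the fit to a single exponential with a degeneracy flag.
At the kinetics regime of interest (τ ≈ 0.5 and 7.5 ms, 85/15 weights,
SNR 50) the median recovery error across 50 replicates is ~1–2% on the time
constants and <1 point on the fast fraction; individual replicates can reach
~10% on the slow τ, which is sampling noise of the estimator, not bias.

**Photobleach correction** fits a free bi-exponential a₁e^{λ₁t}+a₂e^{λ₂t}
(a plateau is the λ→0 limit) by the same variable-projection grid and
divides the trace by the fit normalized to its first sample. The operation
is idempotent to <0.5%; a flat trace is returned unchanged.

**Slow-bleach power-law slope**: 1-Hz zero-phase low-pass, 140× decimation,
drop the first minute, straight-line fit of log₁₀F against log₁₀t. Exact
power laws are recovered to <0.005 in the exponent.

**ΔF/F₀ conventions.** Three baselines coexist in the package because the
acquisition schemes differ: (i) high-pass at 0.5 Hz then divide by the trace
mean (single-cell kHz recordings, in %); (ii) a 3rd-degree polynomial fit
that excludes caller-masked frames (running) and, after one refit iteration,
frames more than 2 SD above the fit — the reported signal is
−ΔF/F = max(ΔF/F) − ΔF/F, which is exactly ≥ 0 with its minimum at the
brightest point and depolarization positive; (iii) a centered rolling
5th-percentile baseline over a 20-minute window after inversion and 5-Hz
low-pass (slow resonant-scanning recordings). "Inversion" is implemented as
reflection about the trace mean (y = 2·mean − x): plain negation would make
any positive fluorescence trace's percentile baseline negative and the
normalization ill-defined, while reflection keeps F₀ positive and
depolarization positive. Edge windows are truncated; a window longer than
the trace falls back to one global percentile.

## Spike detection

Detection runs on depolarization-positive %ΔF/F₀ at ≥2 kHz and requires
three statistics to exceed z = 3 simultaneously. All z-scores use robust
baselines (median and 1.4826·MAD) so the detector is exactly invariant to
offsets and positive rescaling.

* **Metric 1** — 2nd-order Butterworth high-pass at 40 Hz.
* **Metric 2** — a cumulative tail-probability statistic over a trailing
  1.6-ms window: each high-passed sample's robust z maps through the normal
  upper-tail probability (via erf) to a surprisal, capped at the surprisal
  of a 2-SD excursion, and summed over the window. The cap is the decisive
  design element: it makes the statistic measure *how long* the trace stays
  clearly supra-noise rather than how extreme any single sample is, so an
  isolated extreme shot-noise sample (which at 100-photon baselines reaches
  −4 SD routinely within a minute of data) cannot imitate a 2-ms spike. The
  statistic is computed on the high-passed trace because slow subthreshold
  up-states would otherwise saturate it for seconds at a time.
* **Metric 3** — the pointwise product of |detail coefficients| at
  stationary-wavelet (`coif1`, undecimated so all scales share the input
  grid) scales 2–5. Each scale is circularly shifted by its group delay,
  calibrated once per trace length by locating the response peak to a unit
  impulse, so a transient's energy lines up at one index across scales
  ("global realignment"). The product is z-scored in the log domain — where
  it is a sum across scales — against an upper-sided robust scale (median of
  upward deviations), because the raw product's distribution is far too
  heavy-tailed for a two-sided MAD and its long left tail (logs of
  near-zero coefficients) would otherwise drown the informative upper tail.

Candidates within a 2-ms refractory window merge onto the sample with the
largest wavelet metric (the spike peak). The reported onset is metric 1's
last return to baseline (z ≤ 0) before the peak — the point where the spike
leaves the subthreshold level — so amplitudes measured "from the onset
point" are measured from the spike foot. Detections within 50 ms of the
trace ends are discarded (zero-phase filter startup transients corrupt the
metrics there). `SpikeSet` carries both onset and peak times; event-matching
against ground-truth spike centers should use peaks.

At the benchmark conditions (7.2 kHz, 20% spikes of 2-ms FWHM, 2.5% noise,
20 spikes/60 s) the detector operates at recall ≥ 0.99 and precision ≥ 0.95
(±2 ms matching) across seed batches.

**Waveform metrics**: spike-triggered average over a −2 to +8 ms window;
amplitude = STA peak − STA value at the onset sample; FWHM measured on the
STA after linear interpolation to 20 kHz, at half amplitude above the onset
value. **Subthreshold summary**: 0.1–50 Hz bidirectional Butterworth; the
down-state is the 1st percentile of that band, the up-state the band's mean
at spike onsets (99th percentile fallback, flagged, when no spikes were
detected); fluctuation = up − down and dynamic range = fluctuation +
amplitude hold exactly by construction.

## Population tuning

Trialization uses each presentation's own blank baseline (mean raw signal
0.3–0.5 s into the 0.5-s blank), builds a full-length −ΔF/F trace from those
per-presentation baselines, low-passes once (3rd-order, 12-Hz Butterworth,
zero phase) and averages over the 0.5-s stimulus plus the following 0.3 s to
get the subthreshold response R; the mean over the final 0.2 s of the
preceding blank is kept for the evoked test. VE classification: per
direction, a one-sided paired t-test of R against that blank-final mean
across trials, significant if any direction's p < 0.05/8 = 0.00625
(Bonferroni); OS is then a one-way ANOVA of R across the 8 directions at
0.05, evaluated for VE cells only. The paired construction and the
per-direction level were checked by null simulation: with 24 trials the
familywise rate sits at ~5%; with 10 trials the t tails are mildly inflated
(~6%) by weak cross-trial dependence the filtering introduces, so the
calibration simulations use 24 trials.

The bimodal Gaussian tuning fit multi-starts θ_pref at each stimulus
direction and polishes by bounded least squares; `ang()` wraps angular
differences to [0°, 180°]. The model is exactly symmetric under swapping the
two lobes and rotating θ_pref by 180°, so fits are canonicalized to
C_pref ≥ C_oppo. Flat response vectors return a flagged degenerate fit, and
the fitted RSS never exceeds the flat-model RSS. For gOSI, negative mean
responses are clipped to zero (keeping the index in [0, 1]); an all-zero
vector yields NaN.

Neuropil masks grow by 8-connected one-pixel dilations around the ROI,
excluding all ROI pixels and the brightest 4% of the field (puncta),
stopping at the first ring that brings the mask past 300 pixels (the full
ring is kept). Subtraction is F_raw − 0.7·F_neuropil; ROIs whose mean
neuropil fluorescence exceeds 1.1× the mean raw fluorescence are excluded
(the rule is evaluated on trace means).

## Ripples

Detection: 4th-order zero-phase Bessel band-pass at 130–200 Hz, analytic
envelope, onsets at upward crossings of mean + 3 SD of the envelope,
crossings within 20 ms merged. Thresholding in SD units makes detection
invariant to LFP scaling. The threshold statistics use the whole session.
Onset clustering is DBSCAN with eps = 1 s and a minimum neighbourhood of one
point, which reduces to chaining consecutive onsets with gaps ≤ 1 s; single
events form singleton clusters and the first onset of each cluster is the
representative. Framewise ripple power is the mean envelope per frame
interval, divided by the whole-series SD (all zeros, flagged, if the SD is
zero).

Peri-event averaging assigns every imaging frame to at most one
representative event — the nearest event whose window (default −0.3 to
+0.4 s) covers it, earlier event on ties — so overlapping windows never
double-count a frame; non-immobile frames are excluded when a mask is given.
Cell means average across that cell's events, the grand mean across cells,
and the SEM uses animals as the unit of replication (undefined with one
animal). Response quantification takes the argmax/argmin of the post-onset
grand average, averages each cell over a 50-ms window centred there,
subtracts the cell's −200…−100 ms baseline, and tests the animal-wise means
one-sided against zero (greater for the peak, less for the trough). Because
the extremum locations are chosen from the same data, a pure-noise session
gives mildly optimistic peak estimates; the tests remain calibrated at the
animal level for the effect sizes of interest.

## Pupil phase

Running bouts are supra-threshold (1 cm/s) stretches of ≥ 1 s; bouts
separated by less than 3 s are consolidated. Pupil periods are the monotone
stretches between local extrema of the 0.5-Hz-smoothed diameter trace,
classified dilation/constriction, and kept only if ≥ 1 s, mean speed
> 0.02 mm/s, ≤ 15% NaN, and ≥ 3 s away from any running bout. The pupil
phase is the analytic-signal argument of the 0.1–1 Hz band-passed,
mean-subtracted diameter: 0 at maximum dilation, ±π at minimum, dilation in
(−π, 0). Phase profiles bin a signal into 65 bins over [−π, π) (left-closed;
π joins the last bin), smooth circularly with a 3-bin rolling mean and
centre by subtracting the profile mean. Per-bin SEM is computed over samples
by default; a per-period mode (SEM across per-period bin means) is provided
and is the calibrated choice for autocorrelated signals such as the 2–10 Hz
Hilbert amplitude — the null-coupling flatness check uses it. The 2–10 Hz
amplitude channel is: Hamming FIR band-pass 2–10 Hz, analytic envelope,
then a 0.1–1 Hz band-pass of the envelope.

## Screening metrics

Background per channel is the mode of a 256-bin intensity histogram of the
first frame. The membrane mask thresholds the first-frame composite (mean of
both background-subtracted channels) at the 90th percentile of non-saturated
pixels; saturated pixels never enter the mask. Relative brightness is the
green/red ratio of the first-20-frame means; photostability is the
trapezoidal area under F(t)/F(0), normalized across a comparison set to the
maximal area (so values lie in (0, 1] and rankings are invariant to common
rescaling); response amplitudes are per-stimulation peak |ΔF/F₀| in a 100-ms
post-onset window, averaged FOV → well → variant. The compound metrics are
identities asserted on construction: index = response·√brightness,
budget = index·√photostability. Excitation-spectra power correction assumes
two-photon (quadratic) dependence: F·(target/measured)².

## Synthetic data: what it emulates, and what it does not

All generators draw from one `numpy` PCG64 generator per call (per-cell
sub-streams split via `SeedSequence.spawn`), so identical configuration and
seed give bit-identical output.

* **Voltage traces**: photons = baseline · bleach(t) · (1 + spikes + sub) +
  noise, with Gaussian spike transients of stated FWHM (negative-going,
  default −20%, 2 ms), band-limited Gaussian subthreshold fluctuations
  (0.1–50 Hz, 4% SD — peak excursions ≈ ±10%), bi-exponential bleaching
  (30% at τ = 5 s over 70% at τ = 500 s) and additive noise whose SD is a
  fixed fraction (2.5%) of the *local bleached* baseline, as photon noise
  scales with collected intensity (a Poisson mode exists behind a flag).
  Spike count is Poisson (default 20/60 s); spike positions are drawn from
  the dimmest quintile of the fluorescence subthreshold component, because
  cells fire from depolarized up-states and a negative-going indicator is
  dimmest there — this is what gives the up-state/down-state summary its
  meaning. Uniform placement is available (`spikes_at_upstate=False`).
  The generator does not model the indicator photocycle, spike-shape
  asymmetry (real action potentials rise faster than they fall), movement
  artifacts, or pixel-level imaging.
* **Population sessions**: 0.5-s blank + 0.5-s grating per presentation, 8
  directions shuffled within each trial; a cell's fluorescence dips by its
  bimodal-Gaussian response during the stimulus and the 0.3 s after; all
  cells share a slow common-mode trace (brain state) and a neuropil trace
  mixed in at weight 0.7. The default cohort mirrors the study scale: 95
  cells, 88 with evoked responses, 47 of those orientation-tuned.
* **LFP**: spectrally shaped 1/f noise plus ripple bursts — a 160-Hz
  sinusoid under an asymmetric Gaussian window (2.5-ms rise, 15-ms decay,
  ~50 ms total), with amplitude in multiples of the measured 130–200 Hz
  background SD (default 8). The emitted ground-truth time of each burst is
  its *expected detection onset*: the point where the band-filtered envelope
  of a noiseless prototype burst crosses the Rayleigh mean + 3 SD level, so
  detection error measures the detector, not the arbitrary phase of the
  window.
* **Pupil sessions**: diameter 1 + 0.2·cos(2πt/T) mm (default T = 6 s, a
  realistic quiet-wakefulness cycle that also sits comfortably inside the
  0.1–1 Hz analysis band), 2–10 Hz band noise whose envelope is
  1 + depth·cos(phase − φ₀), optional running bouts at 5 cm/s, and NaN
  dropouts at a stated fraction. Coupling recovery to ±1 of 65 bins needs
  long sessions; the recovery checks use 40-minute sessions, comparable to
  real recording durations.

Passing tests on these generators demonstrates that the pipeline recovers
what it is designed to recover under its own model assumptions; they do not
certify performance under motion artifacts, non-stationary noise, overlapping
cells or indicator nonlinearities, none of which are emulated.

## Problem sizes in the shipped checks

The validation suites run at sizes chosen to make their statistics
meaningful while staying desk-scale: the spike-detector operating point uses
ten 60-s sessions at 7.2 kHz; the VE null calibration uses 50 sessions of
20 cells × 24 trials; kinetics recovery uses 50 replicates (20 in the
summary script); pupil coupling uses 40-minute sessions (ten in the test
suite, five in the summary script); ripple timing uses five 60-s sessions.

## Known limitations

* The three-metric detector's wavelet statistic has modest margin on
  perfectly Gaussian (symmetric) spike shapes, whose energy misses the
  finest wavelet scale; real optical spikes, with their fast rising edge,
  light up scales 2–3 more strongly. The capped metric-2 construction
  carries more of the discrimination in the synthetic setting.
* The VE t-test's familywise error is mildly anti-conservative below ~15
  trials (see above).
* Peri-event peak/trough locations are data-selected extrema and carry the
  usual selection bias on null data.
* `ewma_smooth` is provided for visualization only and is never used in any
  quantification path.
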