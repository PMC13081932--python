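"""Three-metric optical spike detection and waveform/subthreshold metrics.

Detection runs on depolarization-positive %ΔF/F₀ traces sampled at ≥ 2 kHz
(negative-going indicator traces must be negated by the caller).  Three
z-scored statistics must simultaneously exceed the threshold (default 3):

1. a 40-Hz high-pass of the trace (2nd-order Butterworth, zero phase) —
   fast transient energy;
2. a cumulative tail-probability statistic over a sliding 1.6-ms window —
   each sample of the high-passed trace maps through the normal (erf-based)
   upper-tail probability to a surprisal, summed over the trailing window,
   so excursions sustained for a spike's duration score far higher than
   isolated noise points (slow subthreshold crests, which would otherwise
   saturate this statistic for seconds at a time, are removed by the
   high-pass);
3. the pointwise product of |detail coefficients| at stationary-wavelet
   (coif1) scales 2–5, each scale circularly realigned by its group delay so
   a spike's energy coincides at one index across scales; the product is
   z-scored in the log domain (where it is a sum across scales) against an
   upper-sided robust scale, because the raw product is too heavy-tailed for
   a meaningful MAD.

All three are z-scored against robust baselines (median / 1.4826·MAD) so the
detector is invariant to offset and positive rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import special

from .signal_ops import zero_phase_filter
from .timeseries import TimeSeries

_WAVELET = "coif1"
_SCALES = (2, 3, 4, 5)


@dataclass
class SpikeSet:
    onset_times_s: np.ndarray
    peak_times_s: np.ndarray | None = None
    metric_traces: tuple | None = None
    sta_time_ms: np.ndarray | None = None
    sta_waveform: np.ndarray | None = None
    amplitude_pct: float = np.nan
    fwhm_ms: float = np.nan

    @property
    def n_spikes(self) -> int:
        return len(self.onset_times_s)


@dataclass
class SubthresholdSummary:
    """Down-state, up-state, fluctuation and dynamic range in %ΔF/F₀.

    down-state: 1st percentile of the 0.1–50 Hz band-passed trace;
    up-state: mean band-passed signal at the detected spike onsets;
    fluctuation = up − down; dynamic range = fluctuation + spike amplitude.
    """

    down_state_pct: float
    up_state_pct: float
    amplitude_pct: float
    up_state_fallback: bool = False

    @property
    def fluctuation_pct(self) -> float:
        return self.up_state_pct - self.down_state_pct

    @property
    def dynamic_range_pct(self) -> float:
        return self.fluctuation_pct + self.amplitude_pct


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def _robust_z_upper(x: np.ndarray) -> np.ndarray:
    """Robust z using only upward deviations for the scale.

    Appropriate for statistics with a long *left* tail (e.g. log products of
    wavelet magnitudes) where the two-sided MAD would be dominated by the
    uninformative lower tail.
    """
    med = np.median(x)
    upper = x[x > med] - med
    scale = 1.4826 * np.median(upper) if upper.size else 0.0
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


_shift_cache: dict = {}


def _swt_scale_shifts(n: int) -> dict:
    """Group-delay realignment shifts per SWT scale, via impulse calibration.

    Feeds a unit impulse at the centre of an ``n``-sample signal and records
    where each scale's |detail| peaks; shifting by the offset makes all
    scales peak at the impulse index ("global realignment").
    """
    key = (n, _WAVELET, _SCALES)
    if key in _shift_cache:
        return _shift_cache[key]
    probe = np.zeros(n)
    center = n // 2
    probe[center] = 1.0
    coeffs = pywt.swt(probe, _WAVELET, level=max(_SCALES), trim_approx=True, norm=True)
    shifts = {}
    for s in _SCALES:
        detail = np.abs(coeffs[-s])
        shifts[s] = center - int(np.argmax(detail))
    _shift_cache[key] = shifts
    return shifts


def _pad_pow2(x: np.ndarray, level: int):
    m = 2 ** level
    pad = (-len(x)) % m
    if pad:
        x = np.concatenate([x, x[-1] + np.zeros(pad)])
    return x, pad


def compute_detection_metrics(dff: TimeSeries, erf_window_ms: float = 1.6,
                              surprisal_cap_z: float = 2.0):
    """The three z-scored detection statistics (same length/rate as input).

    ``surprisal_cap_z`` caps each sample's contribution to the windowed
    tail-probability statistic at the surprisal of a ``z``-level excursion,
    so metric 2 counts how long the signal stays clearly supra-noise rather
    than how extreme any single sample is.
    """
    if dff.rate_hz < 2000:
        raise ValueError("spike detection needs >= 2 kHz sampling")
    x = dff.values
    if np.isnan(x).any():
        raise ValueError("NaNs in spike-detection input")

    if np.ptp(x) == 0:
        zeros = dff.copy(values=np.zeros_like(x))
        return zeros, zeros.copy(), zeros.copy()

    # Metric 1: 40-Hz high-pass, robust z
    hp = zero_phase_filter(dff, "butterworth", "highpass", 2, 40.0)
    m1 = _robust_z(hp.values)

    # Metric 2: cumulative tail-probability of the high-passed trace over the
    # trailing 1.6-ms window (the high-pass removes slow subthreshold crests
    # that would otherwise keep the statistic saturated for seconds).  Each
    # sample's surprisal is capped at the threshold-level value so a single
    # extreme shot-noise sample cannot imitate a sustained 1.6-ms excursion:
    # the statistic measures duration, not isolated amplitude.
    tail = 0.5 * special.erfc(m1 / np.sqrt(2.0))     # upper-tail normal prob
    cap = -np.log(0.5 * special.erfc(surprisal_cap_z / np.sqrt(2.0)))
    surprisal = np.minimum(-np.log(np.clip(tail, 1e-300, 1.0)), cap)
    win = max(int(round(erf_window_ms * 1e-3 * dff.rate_hz)), 2)
    kernel = np.ones(win)
    csum = np.convolve(surprisal, kernel, mode="full")[:len(x)]
    m2 = _robust_z(csum)

    # Metric 3: realigned SWT coif1 detail product, scales 2-5, z-scored in
    # the log domain with an upper-sided robust scale
    padded, pad = _pad_pow2(x, max(_SCALES))
    coeffs = pywt.swt(padded, _WAVELET, level=max(_SCALES), trim_approx=True, norm=True)
    shifts = _swt_scale_shifts(len(padded))
    log_prod = np.zeros(len(padded))
    for s in _SCALES:
        detail = np.abs(coeffs[-s])
        log_prod += np.log(np.clip(np.roll(detail, shifts[s]), 1e-300, None))
    if pad:
        log_prod = log_prod[:-pad]
    m3 = _robust_z_upper(log_prod)

    mk = lambda v: dff.copy(values=v, units="z")
    return mk(m1), mk(m2), mk(m3)


def detect_spikes(dff: TimeSeries, z_thresh: float = 3.0,
                  refractory_ms: float = 2.0, onset_z: float = 0.0,
                  edge_exclude_ms: float = 50.0) -> SpikeSet:
    """Samples where all three metrics exceed ``z_thresh``, merged and timed.

    Candidates within the refractory window collapse onto the sample with the
    largest wavelet-product metric (the spike peak); the reported onset is
    the last sub-threshold crossing of metric 1 before that peak — by default
    its return to baseline (z ≤ 0), i.e. the point where the spike departs
    from the subthreshold level, so waveform amplitude is measured from the
    spike foot.  Candidates within ``edge_exclude_ms`` of either end are
    discarded (zero-phase filter startup transients corrupt the metrics
    there).
    """
    m1, m2, m3 = compute_detection_metrics(dff)
    above = (m1.values > z_thresh) & (m2.values > z_thresh) & (m3.values > z_thresh)
    edge = int(round(edge_exclude_ms * 1e-3 * dff.rate_hz))
    if edge > 0:
        above[:edge] = False
        above[len(above) - edge:] = False
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return SpikeSet(onset_times_s=np.array([]), peak_times_s=np.array([]),
                        metric_traces=(m1, m2, m3))

    refr = max(int(round(refractory_ms * 1e-3 * dff.rate_hz)), 1)
    groups = np.split(idx, np.flatnonzero(np.diff(idx) > refr) + 1)
    peak_idx = [g[np.argmax(m3.values[g])] for g in groups]

    pairs = []
    lookback = int(round(0.005 * dff.rate_hz))   # search up to 5 ms back
    for p in peak_idx:
        start = max(p - lookback, 0)
        below = np.flatnonzero(m1.values[start:p + 1] <= onset_z)
        onset = start + below[-1] if below.size else p
        pairs.append((onset, p))
    pairs = sorted(set(pairs))
    # enforce the refractory separation on the final onset list
    kept = [pairs[0]]
    for o, p in pairs[1:]:
        if o - kept[-1][0] >= refr:
            kept.append((o, p))
    onsets = np.array([o for o, _ in kept])
    peaks = np.array([p for _, p in kept])
    return SpikeSet(onset_times_s=dff.t0_s + onsets / dff.rate_hz,
                    peak_times_s=dff.t0_s + peaks / dff.rate_hz,
                    metric_traces=(m1, m2, m3))


def spike_waveform_metrics(dff: TimeSeries, onset_times_s,
                           window_ms=(-2.0, 8.0),
                           interp_rate_hz: float = 20000.0) -> SpikeSet:
    """Spike-triggered average, amplitude and FWHM from detected onsets.

    Amplitude is the STA peak minus the STA value at the onset sample; FWHM
    is measured on the STA after linear interpolation to 20 kHz, as the width
    at half amplitude above the onset value.
    """
    onset_times_s = np.asarray(onset_times_s, dtype=float)
    if onset_times_s.size == 0:
        return SpikeSet(onset_times_s=onset_times_s)

    pre = int(round(-window_ms[0] * 1e-3 * dff.rate_hz))
    post = int(round(window_ms[1] * 1e-3 * dff.rate_hz))
    segs = []
    for t in onset_times_s:
        i = dff.index_at(t)
        if i - pre < 0 or i + post >= len(dff):
            continue
        segs.append(dff.values[i - pre:i + post + 1])
    if not segs:
        return SpikeSet(onset_times_s=np.array([]))
    sta = np.mean(segs, axis=0)
    t_ms = (np.arange(-pre, post + 1) / dff.rate_hz) * 1e3

    onset_val = sta[pre]
    peak_idx = pre + int(np.argmax(sta[pre:]))
    amplitude = sta[peak_idx] - onset_val

    # FWHM on the 20-kHz interpolated STA
    t_fine = np.arange(t_ms[0], t_ms[-1], 1e3 / interp_rate_hz)
    sta_fine = np.interp(t_fine, t_ms, sta)
    half = onset_val + amplitude / 2.0
    above = sta_fine >= half
    peak_fine = int(np.argmin(np.abs(t_fine - t_ms[peak_idx])))
    lo = peak_fine
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_fine
    while hi < len(above) - 1 and above[hi + 1]:
        hi += 1
    fwhm = t_fine[hi] - t_fine[lo] + (t_fine[1] - t_fine[0])

    return SpikeSet(onset_times_s=onset_times_s, sta_time_ms=t_ms, sta_waveform=sta,
                    amplitude_pct=float(amplitude), fwhm_ms=float(fwhm))


def subthreshold_summary(dff: TimeSeries, onset_times_s, amplitude_pct: float,
                         band=(0.1, 50.0)) -> SubthresholdSummary:
    """Down/up state, subthreshold fluctuation and dynamic range.

    The trace is band-passed 0.1–50 Hz (bidirectional Butterworth); the
    down-state is its 1st percentile and the up-state the mean at spike
    onsets.  Without detected spikes the 99th percentile substitutes for the
    up-state and the result is flagged.
    """
    filt = zero_phase_filter(dff, "butterworth", "bandpass", 2, band)
    down = float(np.percentile(filt.values, 1.0))
    onset_times_s = np.asarray(onset_times_s, dtype=float)
    if onset_times_s.size:
        idx = np.array([filt.index_at(t) for t in onset_times_s])
        up = float(np.mean(filt.values[idx]))
        fallback = False
    else:
        up = float(np.percentile(filt.values, 99.0))
        fallback = True
    return SubthresholdSummary(down_state_pct=down, up_state_pct=up,
                               amplitude_pct=float(amplitude_pct),
                               up_state_fallback=fallback)
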