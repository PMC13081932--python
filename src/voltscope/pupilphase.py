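"""Behavioral segmentation and pupil-phase binning of voltage dynamics.

Quiet-wakefulness brain state is tracked through the pupil: the diameter
trace is split into dilation/constriction periods, periods contaminated by
running (±3 s), slow drift (|mean speed| ≤ 0.02 mm/s), short duration
(< 1 s) or tracking dropouts (> 15% NaN) are discarded, and fluorescence
(ΔF/F₀ or its 2–10 Hz Hilbert amplitude) is binned against the pupil's
instantaneous phase into a 65-bin canonical dilation/constriction cycle.

Phase convention: 0 at maximum diameter, ±π at minimum; dilation occupies
(−π, 0) and constriction (0, π).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_ops import _interpolate_nans, hilbert_analytic, zero_phase_filter
from .timeseries import TimeSeries


@dataclass
class PupilPeriod:
    start_s: float
    end_s: float
    kind: str                    # "dilation" | "constriction"
    mean_speed_mm_s: float
    nan_frac: float
    valid: bool


@dataclass
class BehaviorSegments:
    running: list
    pupil_periods: list

    @property
    def valid_periods(self):
        return [p for p in self.pupil_periods if p.valid]


@dataclass
class PhaseProfile:
    bin_centers: np.ndarray
    mean: np.ndarray             # smoothed, centred
    sem: np.ndarray
    count: np.ndarray
    mean_raw: np.ndarray         # per-bin means before smoothing/centring
    smoothed: bool = True
    centered: bool = True


def detect_running(velocity: TimeSeries, thresh: float = 1.0,
                   min_dur_s: float = 1.0, merge_gap_s: float = 3.0) -> list:
    """Running bouts: ≥ ``min_dur_s`` above ``thresh`` cm/s, gaps < 3 s merged."""
    v = velocity.values
    above = np.nan_to_num(v, nan=0.0) > thresh
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(v))
    bouts = [(velocity.t0_s + s / velocity.rate_hz, velocity.t0_s + e / velocity.rate_hz)
             for s, e in zip(starts, stops) if (e - s) / velocity.rate_hz >= min_dur_s]
    merged = []
    for b in bouts:
        if merged and b[0] - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    return merged


def detect_pupil_periods(pupil: TimeSeries, running: list,
                         min_dur_s: float = 1.0, min_speed_mm_s: float = 0.02,
                         max_nan_frac: float = 0.15, run_margin_s: float = 3.0,
                         smooth_hz: float = 0.5) -> BehaviorSegments:
    """Split the pupil trace into valid dilation/constriction periods.

    Local extrema of the smoothed (NaN-interpolated, ``smooth_hz`` low-pass)
    diameter delimit monotone stretches; each stretch is classified by sign
    of the diameter change and invalidated when too short, too slow, too
    NaN-ridden, or within ``run_margin_s`` of a running bout.
    """
    if np.isnan(pupil.values).all():
        raise ValueError("pupil trace entirely NaN")
    smooth = zero_phase_filter(pupil, "butterworth", "lowpass", 2, smooth_hz)
    y = _interpolate_nans(smooth.values, pupil.rate_hz)

    dy = np.sign(np.diff(y))
    dy[dy == 0] = 1
    turns = np.flatnonzero(np.diff(dy) != 0) + 1
    bounds = np.concatenate([[0], turns, [len(y) - 1]])

    periods = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if i1 <= i0:
            continue
        t0 = pupil.t0_s + i0 / pupil.rate_hz
        t1 = pupil.t0_s + i1 / pupil.rate_hz
        dur = t1 - t0
        delta = y[i1] - y[i0]
        speed = delta / dur if dur > 0 else 0.0
        seg = pupil.values[i0:i1 + 1]
        nan_frac = float(np.isnan(seg).mean())
        near_running = any(t0 < rb[1] + run_margin_s and t1 > rb[0] - run_margin_s
                           for rb in running)
        valid = (dur >= min_dur_s and abs(speed) > min_speed_mm_s
                 and nan_frac <= max_nan_frac and not near_running)
        periods.append(PupilPeriod(start_s=t0, end_s=t1,
                                   kind="dilation" if delta > 0 else "constriction",
                                   mean_speed_mm_s=float(speed),
                                   nan_frac=nan_frac, valid=valid))
    return BehaviorSegments(running=list(running), pupil_periods=periods)


def pupil_phase(pupil: TimeSeries, band=(0.1, 1.0)) -> TimeSeries:
    """Instantaneous pupil phase via the analytic signal of the band-passed trace.

    Returns radians in [−π, π): 0 at maximum diameter, ±π at minimum,
    dilation in (−π, 0), constriction in (0, π).
    """
    if band[0] <= 0 or band[1] >= pupil.rate_hz / 2:
        raise ValueError("invalid pupil phase band")
    filled = pupil.copy(values=_interpolate_nans(pupil.values, pupil.rate_hz))
    filled.values -= filled.values.mean()
    bp = zero_phase_filter(filled, "butterworth", "bandpass", 2, band)
    _, phase = hilbert_analytic(bp)
    return phase


def phase_bin(sig: TimeSeries, phase: TimeSeries, periods: BehaviorSegments | None = None,
              n_bins: int = 65, smooth: bool = True, center: bool = True,
              sem_mode: str = "samples") -> PhaseProfile:
    """Bin a signal by pupil phase into ``n_bins`` bins over [−π, π).

    Only samples inside valid pupil periods enter (all samples when
    ``periods`` is None).  Per-bin mean and SEM; the mean profile is
    circularly smoothed with a rolling window of 3 and centred by
    subtracting its mean.  Empty bins report count 0 and NaN mean.

    ``sem_mode='samples'`` treats samples as independent;
    ``sem_mode='periods'`` computes the SEM across per-period bin means,
    which stays calibrated when the signal is autocorrelated within a
    period (requires ``periods``).
    """
    if len(sig) != len(phase):
        raise ValueError("signal and phase must share the sample clock")
    if sem_mode not in ("samples", "periods"):
        raise ValueError("sem_mode must be 'samples' or 'periods'")
    if sem_mode == "periods" and periods is None:
        raise ValueError("per-period SEM needs pupil periods")
    use = np.zeros(len(sig), dtype=bool)
    block = np.zeros(len(sig), dtype=int)
    if periods is None:
        use[:] = True
    else:
        for k, p in enumerate(periods.valid_periods):
            i0 = sig.index_at(p.start_s)
            i1 = sig.index_at(p.end_s)
            use[i0:i1 + 1] = True
            block[i0:i1 + 1] = k
    use &= ~np.isnan(sig.values) & ~np.isnan(phase.values)

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.digitize(phase.values[use], edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)        # right edge π joins the last bin
    vals = sig.values[use]
    blocks = block[use]

    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        in_bin = idx == b
        sel = vals[in_bin]
        count[b] = sel.size
        if not sel.size:
            continue
        mean[b] = sel.mean()
        if sem_mode == "samples":
            sem[b] = sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else np.nan
        else:
            bm = [vals[in_bin & (blocks == k)].mean()
                  for k in np.unique(blocks[in_bin])]
            if len(bm) > 1:
                sem[b] = np.std(bm, ddof=1) / np.sqrt(len(bm))

    profile = mean.copy()
    if smooth:
        padded = np.concatenate([profile[-1:], profile, profile[:1]])
        with np.errstate(invalid="ignore"):
            profile = np.array([np.nanmean(padded[i:i + 3]) for i in range(n_bins)])
    if center:
        profile = profile - np.nanmean(profile)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PhaseProfile(bin_centers=centers, mean=profile, sem=sem, count=count,
                        mean_raw=mean, smoothed=smooth, centered=center)


def band_amplitude_profile(dff: TimeSeries, band=(2.0, 10.0),
                           amp_band=(0.1, 1.0)) -> TimeSeries:
    """Slow envelope of the 2–10 Hz component of a depolarization-positive trace.

    Zero-phase Hamming FIR band-pass at ``band``, analytic-signal amplitude,
    then a second zero-phase band-pass of the amplitude at ``amp_band`` to
    match pupil timescales.  The output is the input to phase binning for the
    Δ 2–10 Hz amplitude profile.
    """
    if dff.duration_s < 20.0:
        raise ValueError("trace shorter than 20 s cannot support the 0.1-Hz corner")
    # 4 periods of the lowest band frequency keep the transition band narrow
    ntaps = min(int(4 * dff.rate_hz / band[0]) | 1, (len(dff) // 3) | 1)
    bp = zero_phase_filter(dff, "hamming_fir", "bandpass", ntaps, band)
    env, _ = hilbert_analytic(bp)
    ntaps2 = min(int(4 * dff.rate_hz / amp_band[0]) | 1, (len(dff) // 3) | 1)
    return zero_phase_filter(env, "hamming_fir", "bandpass", ntaps2, amp_band)
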