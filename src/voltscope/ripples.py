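"""Sharp-wave-ripple detection and event-locked fluorescence statistics.

LFP traces are band-passed in the ripple band (130–200 Hz, zero-phase
Bessel), the analytic-signal envelope thresholded at mean + 3 SD to define
event onsets, onsets clustered (DBSCAN, eps = 1 s) so bursts of ripples
contribute once, and peri-event averages of −ΔF/F built such that each
imaging frame enters at most one event window.  Statistics are computed at
the animal level (SEM and one-sided t-tests with animals as replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import DBSCAN

from .signal_ops import hilbert_analytic, zero_phase_filter
from .timeseries import TimeSeries


@dataclass
class EventSet:
    onset_times_s: np.ndarray
    peak_envelope_sd: np.ndarray | None = None
    cluster_id: np.ndarray | None = None
    is_representative: np.ndarray | None = None

    @property
    def representatives_s(self) -> np.ndarray:
        if self.is_representative is None:
            return self.onset_times_s
        return self.onset_times_s[self.is_representative]


@dataclass
class PeriEventResult:
    time_s: np.ndarray                     # relative to onset
    cell_means: np.ndarray                 # (n_cells, n_bins)
    grand_mean: np.ndarray
    sem: np.ndarray                        # over animals; NaN with one animal
    animal_ids: np.ndarray                 # per cell
    frame_rate_hz: float


def detect_ripples(lfp: TimeSeries, band=(130.0, 200.0), thresh_sd: float = 3.0,
                   order: int = 4, merge_ms: float = 20.0) -> EventSet:
    """Envelope threshold crossings of the ripple-band LFP.

    Onsets are upward crossings of mean + ``thresh_sd``·SD of the Hilbert
    envelope; crossings within ``merge_ms`` merge into one event.  The
    threshold is in envelope SD units, so detection is invariant to scaling
    the LFP.
    """
    if lfp.duration_s < 1.0:
        raise ValueError("LFP trace shorter than 1 s")
    filt = zero_phase_filter(lfp, "bessel", "bandpass", order, band)
    env, _ = hilbert_analytic(filt)
    e = env.values
    mu, sd = e.mean(), e.std()
    if not np.isfinite(thresh_sd):
        return EventSet(onset_times_s=np.array([]), peak_envelope_sd=np.array([]))
    level = mu + thresh_sd * sd

    above = e > level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return EventSet(onset_times_s=np.array([]), peak_envelope_sd=np.array([]))

    merge = max(int(round(merge_ms * 1e-3 * lfp.rate_hz)), 1)
    groups = np.split(crossings, np.flatnonzero(np.diff(crossings) > merge) + 1)
    onsets, peaks = [], []
    for g in groups:
        i = g[0]
        # event extent: until the envelope falls back below the threshold
        j = i
        while j < e.size and e[j] > level:
            j += 1
        onsets.append(lfp.t0_s + i / lfp.rate_hz)
        peaks.append((e[i:max(j, i + 1)].max() - mu) / sd if sd > 0 else np.nan)
    return EventSet(onset_times_s=np.asarray(onsets), peak_envelope_sd=np.asarray(peaks))


def cluster_onsets(events: EventSet, eps_s: float = 1.0) -> EventSet:
    """DBSCAN (min neighbourhood 1) on 1-D onset times; label representatives.

    With a minimum neighbourhood of one point every onset is core, so
    clusters are the chains of onsets with consecutive gaps ≤ ``eps_s``;
    single events form singleton clusters.  Representatives are the first
    onset of each cluster (single events and first-of-cluster).
    """
    onsets = np.asarray(events.onset_times_s, dtype=float)
    if onsets.size == 0:
        return EventSet(onset_times_s=onsets, peak_envelope_sd=events.peak_envelope_sd,
                        cluster_id=np.array([], dtype=int),
                        is_representative=np.array([], dtype=bool))
    labels = DBSCAN(eps=eps_s, min_samples=1).fit_predict(onsets.reshape(-1, 1))
    rep = np.zeros(onsets.size, dtype=bool)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        rep[members[np.argmin(onsets[members])]] = True
    return EventSet(onset_times_s=onsets, peak_envelope_sd=events.peak_envelope_sd,
                    cluster_id=labels, is_representative=rep)


def framewise_ripple_power(envelope: TimeSeries, frame_times_s) -> TimeSeries:
    """Mean ripple-band envelope per imaging frame, SD-normalized.

    Frame ``i`` covers [frame_times[i], frame_times[i+1]); the last frame
    extends by the median frame interval.  A constant envelope (zero SD)
    yields all zeros.
    """
    ft = np.asarray(frame_times_s, dtype=float)
    if np.any(np.diff(ft) <= 0):
        raise ValueError("frame times must be strictly increasing")
    if ft[0] < envelope.t0_s - 1e-9 or ft[-1] > envelope.t0_s + envelope.duration_s + 1e-9:
        raise ValueError("frames outside envelope support")
    dt = np.median(np.diff(ft)) if ft.size > 1 else envelope.dt
    edges = np.concatenate([ft, [ft[-1] + dt]])
    out = np.empty(ft.size)
    for i in range(ft.size):
        seg = envelope.slice_seconds(edges[i], edges[i + 1])
        out[i] = seg.mean() if seg.size else np.nan
    sd = np.nanstd(out)
    if sd == 0:
        return TimeSeries(np.zeros(ft.size), rate_hz=1.0 / dt, t0_s=ft[0], units="sd")
    return TimeSeries(out / sd, rate_hz=1.0 / dt, t0_s=ft[0], units="sd")


def assign_frames_to_events(frame_times_s, representatives_s, window=(-0.3, 0.4),
                            immobility_mask=None) -> np.ndarray:
    """Event index per frame (−1 = unassigned); each frame used at most once.

    A frame belongs to the event whose window covers it; when several
    windows overlap, the nearest event wins, earlier event on ties.  Frames
    outside every window, or not immobile, stay −1.
    """
    ft = np.asarray(frame_times_s, dtype=float)
    reps = np.asarray(representatives_s, dtype=float)
    assign = np.full(ft.size, -1, dtype=int)
    for i, t in enumerate(ft):
        if immobility_mask is not None and not immobility_mask[i]:
            continue
        rel = t - reps
        inside = np.flatnonzero((rel >= window[0]) & (rel <= window[1]))
        if inside.size == 0:
            continue
        dist = np.abs(rel[inside])
        best = inside[np.lexsort((reps[inside], dist))][0]
        assign[i] = best
    return assign


def peri_event_average(cell_traces: list[TimeSeries], animal_ids,
                       representatives_s, immobility_mask=None,
                       window=(-0.3, 0.4)) -> PeriEventResult:
    """Single-inclusion peri-event average of −ΔF/F around ripple onsets.

    All cell traces must share the frame clock.  Per cell, frames assigned to
    each event fill that event's window row (others stay NaN); the cell mean
    averages across events, the grand mean across cells, and SEM uses the
    number of animals as the sample size (NaN with a single animal).
    """
    reps = np.asarray(representatives_s, dtype=float)
    if reps.size == 0:
        raise ValueError("no representative events")
    ref = cell_traces[0]
    ft = ref.times
    rate = ref.rate_hz
    assign = assign_frames_to_events(ft, reps, window, immobility_mask)

    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    rel_time = np.arange(-n_pre, n_post + 1) / rate

    cell_means = []
    kept_animals = []
    for trace, animal in zip(cell_traces, animal_ids):
        rows = np.full((reps.size, rel_time.size), np.nan)
        for fi, ev in enumerate(assign):
            if ev < 0:
                continue
            bin_idx = int(round((ft[fi] - reps[ev]) * rate)) + n_pre
            if 0 <= bin_idx < rel_time.size:
                rows[ev, bin_idx] = trace.values[fi]
        if np.all(np.isnan(rows)):
            continue  # cell dropped: no included frames
        with np.errstate(invalid="ignore"):
            cell_means.append(np.nanmean(rows, axis=0))
        kept_animals.append(animal)
    if not cell_means:
        raise ValueError("no cell had any included frame")
    cell_means = np.asarray(cell_means)
    kept_animals = np.asarray(kept_animals)

    grand = np.nanmean(cell_means, axis=0)
    animals = np.unique(kept_animals)
    if animals.size > 1:
        per_animal = np.array([np.nanmean(cell_means[kept_animals == a], axis=0)
                               for a in animals])
        sem = np.nanstd(per_animal, axis=0, ddof=1) / np.sqrt(animals.size)
    else:
        sem = np.full_like(grand, np.nan)
    return PeriEventResult(time_s=rel_time, cell_means=cell_means, grand_mean=grand,
                           sem=sem, animal_ids=kept_animals, frame_rate_hz=rate)


def quantify_event_response(result: PeriEventResult, peak_win_ms: float = 50.0,
                            baseline_win_ms=(-200.0, -100.0)) -> dict:
    """Peak/trough responses at the grand-average extrema, animal-level tests.

    Locations are the argmax/argmin of the post-onset grand average; each
    cell's response is its mean over a 50-ms window centred there minus its
    own baseline (−200..−100 ms) mean.  Animal-wise means are tested
    one-sided against zero (greater for the peak, less for the trough).
    """
    t = result.time_s
    post = t > 0
    if not post.any():
        raise ValueError("no post-onset samples")
    g = result.grand_mean.copy()
    g[~post] = np.nan
    peak_t = float(t[np.nanargmax(g)])
    trough_t = float(t[np.nanargmin(g)])

    half = peak_win_ms * 1e-3 / 2.0

    def window_mean(center):
        sel = (t >= center - half) & (t <= center + half)
        with np.errstate(invalid="ignore"):
            return np.nanmean(result.cell_means[:, sel], axis=1)

    base_sel = (t >= baseline_win_ms[0] * 1e-3) & (t <= baseline_win_ms[1] * 1e-3)
    with np.errstate(invalid="ignore"):
        baseline = np.nanmean(result.cell_means[:, base_sel], axis=1)
    peak_resp = window_mean(peak_t) - baseline
    trough_resp = window_mean(trough_t) - baseline

    animals = np.unique(result.animal_ids)
    peak_animal = np.array([np.nanmean(peak_resp[result.animal_ids == a]) for a in animals])
    trough_animal = np.array([np.nanmean(trough_resp[result.animal_ids == a]) for a in animals])
    if animals.size > 1:
        p_peak = float(stats.ttest_1samp(peak_animal, 0.0, alternative="greater").pvalue)
        p_trough = float(stats.ttest_1samp(trough_animal, 0.0, alternative="less").pvalue)
    else:
        p_peak = p_trough = float("nan")
    return {"peak_time_s": peak_t, "trough_time_s": trough_t,
            "peak_responses": peak_resp, "trough_responses": trough_resp,
            "p_peak": p_peak, "p_trough": p_trough,
            "peak_animal_means": peak_animal, "trough_animal_means": trough_animal}
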