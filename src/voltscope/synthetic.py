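"""Synthetic session generators with known ground truth.

Each generator emulates one acquisition scheme of the pipeline so every
downstream stage can be scored without raw recordings:

* :func:`simulate_voltage_trace` — kHz single-cell GEVI photon traces with
  negative-going spikes, band-limited subthreshold fluctuations,
  bi-exponential photobleaching and shot-like noise.
* :func:`simulate_population_session` — trial-structured drifting-grating
  sessions with direction-tuned cells, common-mode activity and neuropil
  contamination.
* :func:`simulate_lfp_with_ripples` — 1/f local field potential with
  130–200 Hz ripple bursts of known onset and amplitude.
* :func:`simulate_pupil_session` — slow pupil dilation/constriction cycles,
  running bouts, NaN dropouts and pupil-phase-coupled 2–10 Hz fluorescence.

All randomness flows from one ``numpy`` generator seeded per call;
per-cell sub-streams are split deterministically, so identical config+seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .population import DIRECTIONS_DEG, bimodal_gaussian
from .timeseries import TimeSeries


@dataclass
class SimConfig:
    """Single-cell voltage-trace generator settings.

    Defaults reproduce the benchmarking conditions of the high-rate
    single-cell recordings: 60 s at 7.2 kHz, 20 spikes of −20% ΔF/F and 2-ms
    FWHM, 0.1–50 Hz subthreshold fluctuations, bi-exponential photobleach and
    2.5% additive noise.
    """

    duration_s: float = 60.0
    rate_hz: float = 7200.0
    seed: int = 0
    spike_rate_hz: float = 20.0 / 60.0
    spike_amp_dff: float = -0.20          # negative-going indicator
    spike_fwhm_ms: float = 2.0
    sub_osc_band_hz: tuple = (0.1, 50.0)
    sub_osc_amp_dff: float = 0.04         # SD of the band-limited fluctuation
    bleach_params: tuple = (0.3, 5.0, 0.7, 500.0)   # (A1, tau1_s, A2, tau2_s)
    noise_sd_dff: float = 0.025
    baseline_photons: float = 100.0
    poisson_noise: bool = False
    # place spikes in depolarized up-states (the dimmest subthreshold
    # stretches of a negative-going indicator); False for uniform placement
    spikes_at_upstate: bool = True

    def validate(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if self.rate_hz <= 2 * self.sub_osc_band_hz[1]:
            raise ValueError("rate must exceed twice the subthreshold band edge")
        a1, _, a2, _ = self.bleach_params
        if a1 < 0 or a2 < 0 or abs(a1 + a2 - 1.0) > 1e-9:
            raise ValueError("bleach amplitudes must be nonnegative and sum to 1")
        if self.spike_rate_hz < 0 or self.noise_sd_dff < 0:
            raise ValueError("rates and noise must be nonnegative")


@dataclass
class GroundTruth:
    """Everything needed to score the stage that consumes a generated session."""

    spike_times_s: np.ndarray | None = None
    ripple_times_s: np.ndarray | None = None
    tuning_params: list | None = None          # per cell (C_off, C_pref, C_oppo, theta_pref, sigma)
    pupil_phase: np.ndarray | None = None      # radians per sample
    coupling_depth: float | None = None
    coupling_phase: float | None = None
    running_bouts: list | None = None
    extras: dict = field(default_factory=dict)


def _gaussian_kernel_train(n: int, rate_hz: float, times_s: np.ndarray,
                           amp: float, fwhm_ms: float) -> np.ndarray:
    """Sum of Gaussian transients of given FWHM at the stated times."""
    out = np.zeros(n)
    sigma_s = fwhm_ms * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = np.arange(n) / rate_hz
    for ts in times_s:
        i0 = max(int((ts - 5 * sigma_s) * rate_hz), 0)
        i1 = min(int((ts + 5 * sigma_s) * rate_hz) + 1, n)
        out[i0:i1] += amp * np.exp(-((t[i0:i1] - ts) ** 2) / (2 * sigma_s ** 2))
    return out


def _band_limited_noise(rng, n, rate_hz, band, sd):
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(2, band, btype="bandpass", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, white)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_voltage_trace(config: SimConfig):
    """Photon-count GEVI trace: baseline × bleach × (1 + spikes + subthreshold) + noise."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz

    sub = _band_limited_noise(rng, n, config.rate_hz, config.sub_osc_band_hz,
                              config.sub_osc_amp_dff)

    n_spikes = rng.poisson(config.spike_rate_hz * config.duration_s)
    margin = 0.05 * config.duration_s
    lo, hi = int(margin * config.rate_hz), int((config.duration_s - margin) * config.rate_hz)
    if config.spikes_at_upstate and np.ptp(sub[lo:hi]) > 0 and n_spikes > 0:
        # spikes fire from depolarized up-states: for a negative-going
        # indicator these are the *dimmest* subthreshold stretches, so
        # sample spike positions from the bottom quintile of the
        # fluorescence-units subthreshold component
        seg = sub[lo:hi]
        w = np.clip(np.quantile(seg, 0.2) - seg, 0.0, None)
        w /= w.sum()
        picks = rng.choice(seg.size, size=min(n_spikes, seg.size), replace=False, p=w)
        spike_times = np.sort((lo + picks) / config.rate_hz)
    else:
        spike_times = np.sort(rng.uniform(margin, config.duration_s - margin, n_spikes))
    # enforce a small refractory separation so transients stay resolvable
    if spike_times.size > 1:
        keep = np.concatenate([[True], np.diff(spike_times) > 0.01])
        spike_times = spike_times[keep]

    spikes = _gaussian_kernel_train(n, config.rate_hz, spike_times,
                                    config.spike_amp_dff, config.spike_fwhm_ms)
    a1, tau1, a2, tau2 = config.bleach_params
    bleach = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    clean = config.baseline_photons * bleach * (1.0 + spikes + sub)
    if config.poisson_noise:
        values = rng.poisson(np.clip(clean, 0, None)).astype(float)
    else:
        # photon noise scales with the collected intensity, so the noise SD
        # stays a fixed fraction of the local (bleached) baseline
        values = clean + config.noise_sd_dff * config.baseline_photons * bleach \
            * rng.standard_normal(n)

    gt = GroundTruth(spike_times_s=spike_times,
                     extras={"subthreshold": sub,              # fluorescence units
                             "sub_dep_pct": -100.0 * sub,      # depolarization-positive %dF/F
                             "spike_amp_dff": config.spike_amp_dff,
                             "bleach": bleach})
    return TimeSeries(values, config.rate_hz, 0.0, "photons"), gt


def default_population_tuning(n_cells: int = 95, n_responsive: int = 88,
                              n_tuned: int = 47, evoked_amp: float = 0.05,
                              sigma_deg: float = 30.0, seed: int = 0) -> list:
    """Per-cell tuning parameters mirroring the study cohort.

    95 imaged cells of which 88 show evoked subthreshold responses and 47 of
    those are orientation tuned; amplitudes in −ΔF/F units.
    """
    rng = np.random.default_rng(seed)
    params = []
    for i in range(n_cells):
        if i < n_tuned:
            params.append((evoked_amp, evoked_amp, 0.4 * evoked_amp,
                           float(rng.uniform(0, 360)), sigma_deg))
        elif i < n_responsive:
            params.append((evoked_amp, 0.0, 0.0, 0.0, sigma_deg))
        else:
            params.append((0.0, 0.0, 0.0, 0.0, sigma_deg))
    return params


def simulate_population_session(n_cells: int = 95, n_trials: int = 10,
                                directions=DIRECTIONS_DEG, tuning_params=None,
                                neuropil_weight: float = 0.7,
                                common_mode_sd: float = 0.01,
                                noise_sd: float = 0.01, rate_hz: float = 400.0,
                                blank_s: float = 0.5, stim_s: float = 0.5,
                                baseline_f: float = 100.0, seed: int = 0):
    """Trial-structured population session with known tuning and neuropil.

    Each presentation is a 0.5-s blank followed by a 0.5-s drifting grating;
    the 8 directions appear once per trial in shuffled order.  A tuned cell's
    fluorescence dips by its bimodal-Gaussian response during the stimulus
    and the 0.3 s after it.  Measured traces are
    ``true + neuropil_weight × shared neuropil trace``.

    Returns ``(measured, true, neuropil, schedule, GroundTruth)`` where the
    trace containers are lists of :class:`TimeSeries` / a single neuropil
    series and ``schedule`` is a DataFrame usable by
    :func:`voltscope.population.trialize_responses`.
    """
    directions = np.asarray(directions, dtype=float)
    if n_trials < 2:
        raise ValueError("need at least two trials per direction")
    if tuning_params is None:
        tuning_params = default_population_tuning(n_cells, seed=seed)
    if len(tuning_params) != n_cells:
        raise ValueError("one tuning parameter tuple per cell required")
    for p in tuning_params:
        if p[4] <= 0:
            raise ValueError("tuning sigma must be positive")

    rng = np.random.default_rng(seed)
    per_trial = len(directions) * (blank_s + stim_s)
    duration = n_trials * per_trial + 0.5
    n = int(round(duration * rate_hz))
    t = np.arange(n) / rate_hz

    rows = []
    for trial in range(n_trials):
        order = rng.permutation(directions)
        for j, d in enumerate(order):
            blank_start = trial * per_trial + j * (blank_s + stim_s)
            rows.append({"blank_start_s": blank_start,
                         "stim_start_s": blank_start + blank_s,
                         "direction_deg": float(d), "trial": trial})
    schedule = pd.DataFrame(rows)

    # shared slow common-mode fluctuation (brain state) and neuropil trace
    common = _band_limited_noise(rng, n, rate_hz, (0.1, 4.0), common_mode_sd)
    neuropil_vals = 0.6 * baseline_f * (1.0 + common + 0.5 * noise_sd * rng.standard_normal(n))
    neuropil = TimeSeries(neuropil_vals, rate_hz, 0.0, "F")

    # stimulus response window: stimulus plus the 0.3 s analysis tail
    resp_kernel = np.zeros(n)
    stim_dir = np.full(n, np.nan)
    for row in schedule.itertuples(index=False):
        i0 = int(round(row.stim_start_s * rate_hz))
        i1 = min(int(round((row.stim_start_s + stim_s + 0.3) * rate_hz)), n)
        resp_kernel[i0:i1] = 1.0
        stim_dir[i0:i1] = row.direction_deg

    child_seeds = np.random.SeedSequence(seed).spawn(n_cells)
    measured, true = [], []
    for ci in range(n_cells):
        crng = np.random.default_rng(child_seeds[ci])
        c_off, c_pref, c_oppo, th_pref, sig = tuning_params[ci]
        resp = np.zeros(n)
        active = resp_kernel > 0
        resp[active] = bimodal_gaussian(stim_dir[active], c_off, c_pref, c_oppo,
                                        th_pref, sig)
        noise = noise_sd * crng.standard_normal(n)
        true_vals = baseline_f * (1.0 - resp + common + noise)
        true_ts = TimeSeries(true_vals, rate_hz, 0.0, "F")
        meas_ts = TimeSeries(true_vals + neuropil_weight * neuropil_vals, rate_hz, 0.0, "F")
        true.append(true_ts)
        measured.append(meas_ts)

    gt = GroundTruth(tuning_params=list(tuning_params),
                     extras={"common_mode": common, "neuropil_weight": neuropil_weight})
    return measured, true, neuropil, schedule, gt


def simulate_lfp_with_ripples(duration_s: float = 60.0, rate_hz: float = 1000.0,
                              ripple_rate_hz: float = 0.2,
                              ripple_freq_hz: float = 160.0,
                              ripple_amp_sd: float = 8.0, seed: int = 0,
                              ripple_times_s=None):
    """1/f LFP noise with asymmetric-Gaussian ripple bursts (~50 ms).

    Burst amplitude is expressed in multiples of the 130–200 Hz background
    SD; the ground-truth time of each burst is its envelope peak, which the
    sharp rise (2.5-ms rise sigma vs 15-ms decay) places within a few
    milliseconds of the detectable onset.
    """
    if ripple_amp_sd < 0:
        raise ValueError("ripple amplitude must be nonnegative")
    if not (130.0 <= ripple_freq_hz <= 200.0):
        raise ValueError("ripple frequency must lie in the 130-200 Hz band")
    if rate_hz < 1000:
        raise ValueError("LFP rate must be at least 1 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    # 1/f background from spectrally shaped white noise
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    shape = np.ones_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    bg = np.fft.irfft(spec * shape, n)
    bg /= bg.std()

    sos = signal.butter(4, (130.0, 200.0), btype="bandpass", fs=rate_hz, output="sos")
    sd_band = signal.sosfiltfilt(sos, bg).std()

    if ripple_times_s is None:
        n_r = rng.poisson(ripple_rate_hz * duration_s)
        times = np.sort(rng.uniform(1.0, max(duration_s - 1.0, 1.0), n_r))
        if times.size > 1:
            times = times[np.concatenate([[True], np.diff(times) > 0.3])]
    else:
        times = np.asarray(ripple_times_s, dtype=float)

    sigma_rise, sigma_fall = 0.0025, 0.015

    def burst(tt):
        env = np.where(tt < 0, np.exp(-tt ** 2 / (2 * sigma_rise ** 2)),
                       np.exp(-tt ** 2 / (2 * sigma_fall ** 2)))
        return env * np.sin(2 * np.pi * ripple_freq_hz * tt)

    lfp = bg.copy()
    for tc in times:
        i0 = max(int((tc - 4 * sigma_rise) * rate_hz), 0)
        i1 = min(int((tc + 4 * sigma_fall) * rate_hz), n)
        lfp[i0:i1] += ripple_amp_sd * sd_band * burst(t[i0:i1] - tc)

    # Ground truth is the *expected detection onset*: where the band-filtered
    # envelope of a noiseless prototype burst crosses the mean + 3 SD level of
    # a Rayleigh-distributed background envelope (in units of the burst peak).
    onset_shift = 0.0
    if times.size and ripple_amp_sd > 0:
        proto = np.zeros(int(rate_hz))           # 1-s window, burst at centre
        tp = (np.arange(proto.size) - proto.size // 2) / rate_hz
        proto += ripple_amp_sd * burst(tp)
        pf = signal.sosfiltfilt(sos, proto)
        env = np.abs(signal.hilbert(pf))
        level = 1.253 + 3 * 0.655                # Rayleigh mean + 3 SD, unit-SD band
        above = np.flatnonzero(env > level)
        if above.size:
            onset_shift = tp[above[0]]
    expected_onsets = times + onset_shift

    gt = GroundTruth(ripple_times_s=expected_onsets,
                     extras={"band_sd": sd_band, "burst_centers_s": times,
                             "onset_shift_s": onset_shift})
    return TimeSeries(lfp, rate_hz, 0.0, "au"), gt


def simulate_pupil_session(duration_s: float = 300.0, rate_hz: float = 50.0,
                           cycle_period_s: float = 6.0, running_bouts=None,
                           nan_frac: float = 0.0, coupling_depth: float = 0.5,
                           coupling_phase: float = 0.0, base_amp_dff: float = 0.02,
                           seed: int = 0):
    """Pupil cycles plus phase-coupled 2–10 Hz fluorescence and running bouts.

    The pupil diameter is ``1 + 0.2·cos(2πt/T)`` mm, so its instantaneous
    phase is 0 at maximum dilation and ±π at minimum, matching the pipeline's
    phase convention.  The ΔF/F channel carries 2–10 Hz band noise whose
    envelope is ``1 + coupling_depth·cos(phase − coupling_phase)``.
    ``running_bouts`` is a list of (start_s, end_s) at 5 cm/s.
    """
    if not (2.0 <= cycle_period_s <= 60.0):
        raise ValueError("cycle period must be 2-60 s")
    if not (0.0 <= nan_frac < 0.5):
        raise ValueError("nan_frac must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    theta = 2.0 * np.pi * t / cycle_period_s
    phase = np.angle(np.exp(1j * theta))          # wrap to [-pi, pi)
    pupil_vals = 1.0 + 0.2 * np.cos(theta)

    carrier = _band_limited_noise(rng, n, rate_hz, (2.0, 10.0), 1.0)
    envelope = 1.0 + coupling_depth * np.cos(phase - coupling_phase)
    dff_vals = base_amp_dff * envelope * carrier \
        + 0.1 * base_amp_dff * rng.standard_normal(n)

    velocity_vals = 0.05 * rng.standard_normal(n)
    running_bouts = running_bouts or []
    for start, stop in running_bouts:
        i0, i1 = int(start * rate_hz), min(int(stop * rate_hz), n)
        velocity_vals[i0:i1] += 5.0

    if nan_frac > 0:
        drop = rng.random(n) < nan_frac
        pupil_vals = pupil_vals.copy()
        pupil_vals[drop] = np.nan

    gt = GroundTruth(pupil_phase=phase, coupling_depth=coupling_depth,
                     coupling_phase=coupling_phase, running_bouts=list(running_bouts),
                     extras={"envelope": envelope, "cycle_period_s": cycle_period_s})
    return (TimeSeries(pupil_vals, rate_hz, 0.0, "mm"),
            TimeSeries(velocity_vals, rate_hz, 0.0, "cm/s"),
            TimeSeries(dff_vals, rate_hz, 0.0, "dF/F"),
            gt)
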