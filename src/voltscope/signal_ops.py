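"""Shared filtering, envelope, baseline and photobleaching primitives.

Every downstream stage (spike detection, ripple detection, pupil-phase
binning, population tuning) builds on the operations here:

* zero-phase IIR/FIR filtering with NaN-gap handling,
* analytic-signal envelope and phase,
* deterministic single/dual exponential fitting with an unknown event onset,
* bi-exponential photobleach correction by division,
* slow-bleach power-law slope on log-log axes,
* the several ΔF/F₀ baseline conventions used by the different acquisition
  schemes (high-pass mean-F₀, polynomial baseline, rolling percentile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal


# --------------------------------------------------------------------------
# NaN handling

def _interpolate_nans(values: np.ndarray, rate_hz: float, max_gap_s: float = 1.0) -> np.ndarray:
    """Linearly interpolate NaN gaps no longer than ``max_gap_s``.

    Gaps longer than the limit are still filled (so filters can run) but the
    caller is expected to re-mask them afterwards; leading/trailing NaNs are
    held at the nearest valid value.
    """
    out = values.astype(float).copy()
    nan = np.isnan(out)
    if not nan.any():
        return out
    if nan.all():
        raise ValueError("signal is entirely NaN")
    idx = np.arange(out.size)
    out[nan] = np.interp(idx[nan], idx[~nan], out[~nan])
    return out


# --------------------------------------------------------------------------
# Zero-phase filtering

_IIR_DESIGNS = {"butterworth": signal.butter, "bessel": signal.bessel}


def zero_phase_filter(ts, design: str, kind: str, order_or_taps: int, cutoffs_hz) -> "TimeSeries":
    """Forward-backward (zero phase shift) filtering.

    Parameters
    ----------
    design : {"butterworth", "bessel", "hamming_fir"}
    kind : {"lowpass", "highpass", "bandpass"}
    order_or_taps : IIR order, or FIR tap count (forced odd).
    cutoffs_hz : scalar for low/highpass, (low, high) for bandpass.

    NaN samples are interpolated before filtering and re-masked afterwards.
    """
    from .timeseries import TimeSeries  # local import avoids cycle in docs builds

    cut = np.atleast_1d(np.asarray(cutoffs_hz, dtype=float))
    nyq = ts.rate_hz / 2.0
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise ValueError(f"cutoffs {cut} must lie strictly inside (0, {nyq}) Hz")
    if kind == "bandpass" and cut.size != 2:
        raise ValueError("bandpass needs two cutoffs")
    if kind in ("lowpass", "highpass") and cut.size != 1:
        raise ValueError(f"{kind} needs a single cutoff")

    nan = np.isnan(ts.values)
    x = _interpolate_nans(ts.values, ts.rate_hz) if nan.any() else ts.values

    if design == "hamming_fir":
        ntaps = int(order_or_taps) | 1  # odd taps -> symmetric, integer delay
        pass_zero = {"lowpass": True, "highpass": False, "bandpass": False}[kind]
        b = signal.firwin(ntaps, cut, window="hamming", pass_zero=pass_zero, fs=ts.rate_hz)
        padlen = min(3 * (ntaps - 1), x.size - 1)
        y = signal.filtfilt(b, [1.0], x, padlen=padlen)
    elif design in _IIR_DESIGNS:
        btype = {"lowpass": "lowpass", "highpass": "highpass", "bandpass": "bandpass"}[kind]
        wn = cut if cut.size > 1 else cut[0]
        sos = _IIR_DESIGNS[design](int(order_or_taps), wn, btype=btype, fs=ts.rate_hz, output="sos")
        y = signal.sosfiltfilt(sos, x)
    else:
        raise ValueError(f"unknown filter design {design!r}")

    if nan.any():
        y = y.copy()
        y[nan] = np.nan
    return TimeSeries(y, ts.rate_hz, ts.t0_s, ts.units)


def hilbert_analytic(ts):
    """Analytic-signal envelope (modulus) and instantaneous phase (argument).

    The input must be NaN-free; interpolate first (the zero-phase filters do
    this for you).
    """
    if np.isnan(ts.values).any():
        raise ValueError("input contains NaNs; interpolate before the Hilbert transform")
    analytic = signal.hilbert(ts.values)
    env = ts.copy(values=np.abs(analytic))
    phase = ts.copy(values=np.angle(analytic), units="rad")
    return env, phase


def ewma_smooth(ts, decay_ms: float):
    """Exponentially weighted moving average (visualization only).

    ``decay_ms`` is the time constant: a step input reaches ~63% of its final
    value after one ``decay_ms``.  Never used for quantification.
    """
    if decay_ms <= 0:
        raise ValueError("decay_ms must be positive")
    tau_samples = decay_ms * 1e-3 * ts.rate_hz
    alpha = 1.0 - np.exp(-1.0 / tau_samples)
    out = pd.Series(ts.values).ewm(alpha=alpha, adjust=False).mean().to_numpy()
    return ts.copy(values=out)


# --------------------------------------------------------------------------
# Exponential fits (step-response kinetics, photobleaching)

@dataclass
class ExpFit:
    """Single or dual exponential step-response fit.

    Model (single): ``F(t) = c + k·exp((t−t0)·lam)`` for ``t > t0``, and
    ``c + k`` for ``t ≤ t0``; the dual model adds ``k2·exp((t−t0)·lam2)``
    (plateau ``c + k + k2``).  ``lam`` is the negative inverse time constant
    of the faster component (|lam| ≥ |lam2|).
    """

    c: float
    k: float
    lam: float
    t0: float
    model: str = "single"
    k2: float = 0.0
    lam2: float = 0.0
    rss: float = np.inf
    degenerate: bool = False

    @property
    def tau_s(self) -> float:
        return np.inf if self.lam == 0 else -1.0 / self.lam

    @property
    def tau2_s(self) -> float:
        return np.inf if self.lam2 == 0 else -1.0 / self.lam2

    @property
    def fast_fraction(self) -> float:
        tot = self.k + self.k2
        return float("nan") if tot == 0 else self.k / tot

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _exp_model(t, self.c, self.k, self.lam, self.t0, self.k2, self.lam2)


def _exp_model(t, c, k, lam, t0, k2=0.0, lam2=0.0):
    dt = t - t0
    post = t > t0
    decay = k * np.exp(np.clip(dt * lam, -700, 50)) + k2 * np.exp(np.clip(dt * lam2, -700, 50))
    return c + np.where(post, decay, k + k2)


def _linear_amplitudes(t, y, t0, lams):
    """Solve the amplitudes (c, k[, k2]) for fixed (t0, lam...) by lstsq."""
    cols = [np.ones_like(t)]
    post = t > t0
    for lam in lams:
        col = np.where(post, np.exp(np.clip((t - t0) * lam, -700, 50)), 1.0)
        cols.append(col)
    A = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def fit_exponential(ts, model: str = "single", crop: tuple[float, float] | None = None) -> ExpFit:
    """Deterministic least-squares exponential fit with unknown onset t0.

    A coarse grid over candidate onsets (11 across the crop window) and
    log-spaced rate constants is scanned first, solving the amplitudes
    linearly at each grid point; the best grid point seeds a single
    ``least_squares`` polish.  The procedure has no random element, so
    repeated fits are bit-identical.
    """
    if model not in ("single", "dual"):
        raise ValueError("model must be 'single' or 'dual'")
    t = ts.times
    y = ts.values.astype(float)
    if crop is not None:
        lo, hi = crop
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 8:
            raise ValueError("crop window leaves too few samples")
        t, y = t[sel], y[sel]

    span = y.max() - y.min()
    if span < 1e-12 * max(1.0, abs(y.mean())):
        # constant input: no decay to fit
        return ExpFit(c=float(y.mean()), k=0.0, lam=-1.0, t0=float(t[0]),
                      model=model, rss=0.0, degenerate=True)

    dur = t[-1] - t[0]
    tau_grid = np.geomspace(max(2.0 / ts.rate_hz, dur * 1e-4), dur, 8)
    n_exp = 1 if model == "single" else 2

    def scan(t0_candidates, best=None):
        for t0g in t0_candidates:
            if n_exp == 1:
                for tau in tau_grid:
                    coef, rss = _linear_amplitudes(t, y, t0g, (-1.0 / tau,))
                    if best is None or rss < best[0]:
                        best = (rss, t0g, (-1.0 / tau,), coef)
            else:
                for i, tau1 in enumerate(tau_grid):
                    for tau2 in tau_grid[i + 1:]:
                        lams = (-1.0 / tau1, -1.0 / tau2)
                        coef, rss = _linear_amplitudes(t, y, t0g, lams)
                        if best is None or rss < best[0]:
                            best = (rss, t0g, lams, coef)
        return best

    # coarse onset grid plus a derivative-based onset estimate, then a local
    # refinement pass around the best coarse point
    smooth_n = max(int(len(y) / 200), 1)
    ys = np.convolve(y, np.ones(smooth_n) / smooth_n, mode="same")
    t0_deriv = t[int(np.argmax(np.abs(np.gradient(ys))))]
    coarse = np.concatenate([np.linspace(t[0], t[0] + 0.75 * dur, 11), [t0_deriv]])
    best = scan(coarse)
    step = 0.075 * dur
    # zoom the onset grid until its resolution is a few samples
    while step > 2.0 / ts.rate_hz:
        best = scan(np.linspace(best[1] - step, best[1] + step, 11), best)
        step /= 5.0
    _, t0g, lams, coef = best

    # Polish all parameters jointly from the best grid start.
    if n_exp == 1:
        p0 = [coef[0], coef[1], lams[0], t0g]

        def resid(p):
            return _exp_model(t, p[0], p[1], p[2], p[3]) - y
    else:
        p0 = [coef[0], coef[1], lams[0], t0g, coef[2], lams[1]]

        def resid(p):
            return _exp_model(t, p[0], p[1], p[2], p[3], p[4], p[5]) - y

    scale = max(span, 1e-9)
    sol = optimize.least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14, max_nfev=20000)
    p = sol.x
    rss = float(sol.fun @ sol.fun)

    if n_exp == 1:
        fit = ExpFit(c=p[0], k=p[1], lam=p[2], t0=p[3], model="single", rss=rss)
    else:
        k, lam, k2, lam2 = p[1], p[2], p[4], p[5]
        if abs(lam) < abs(lam2):  # list the fast component first
            k, k2, lam, lam2 = k2, k, lam2, lam
        if abs(k2) < 1e-6 * abs(k):
            # degenerate second component -> effectively a single exponential
            fit = ExpFit(c=p[0], k=k + k2, lam=lam, t0=p[3], model="single",
                         rss=rss, degenerate=True)
        else:
            fit = ExpFit(c=p[0], k=k, lam=lam, t0=p[3], model="dual",
                         k2=k2, lam2=lam2, rss=rss)
    if abs(fit.k) + abs(fit.k2) < 1e-9 * max(abs(fit.c), scale):
        fit.degenerate = True
    return fit


def correct_photobleach_biexp(ts):
    """Divide out a bi-exponential photobleach trend.

    Fits ``B(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2)`` (τ2 may be effectively
    infinite, i.e. a plateau) to the full trace and returns
    ``corrected = raw / (B(t)/B(t0))`` together with the fit.  On a flat or
    degenerate trace the input is returned unchanged.
    """
    t = ts.times
    y = ts.values.astype(float)
    if np.isnan(y).any():
        y = _interpolate_nans(y, ts.rate_hz)

    span = y.max() - y.min()
    if span < 1e-12 * max(1.0, abs(y.mean())):
        fit = ExpFit(c=float(y.mean()), k=0.0, lam=-1.0, t0=float(t[0]),
                     model="dual", rss=0.0, degenerate=True)
        return ts.copy(), fit

    dur = t[-1] - t[0]
    tau_grid = np.geomspace(dur / 300.0, dur * 30.0, 12)
    best = None
    for i, tau1 in enumerate(tau_grid):
        for tau2 in tau_grid[i + 1:]:
            lams = (-1.0 / tau1, -1.0 / tau2)
            coef, rss = _linear_amplitudes(t, y, t[0] - 1.0 / ts.rate_hz, lams)
            if best is None or rss < best[0]:
                best = (rss, lams, coef)
    _, lams, coef = best

    def resid(p):
        return p[0] * np.exp(np.clip(t * p[1], -700, 50)) + \
            p[2] * np.exp(np.clip(t * p[3], -700, 50)) - y

    p0 = [coef[1], lams[0], coef[2] + coef[0], lams[1]]
    sol = optimize.least_squares(resid, p0, method="lm", xtol=1e-13, ftol=1e-13,
                                 max_nfev=20000)
    a1, l1, a2, l2 = sol.x
    if abs(l1) < abs(l2):
        a1, a2, l1, l2 = a2, a1, l2, l1
    rss = float(sol.fun @ sol.fun)
    fit = ExpFit(c=0.0, k=a1, lam=l1, t0=float(t[0]), model="dual",
                 k2=a2, lam2=l2, rss=rss)

    trend = a1 * np.exp(np.clip(t * l1, -700, 50)) + a2 * np.exp(np.clip(t * l2, -700, 50))
    norm = trend / trend[0]
    if np.any(norm <= 0):
        raise ValueError("photobleach fit crosses zero; cannot divide")
    corrected = ts.values / norm
    return ts.copy(values=corrected), fit


def slow_bleach_powerlaw_slope(ts, skip_s: float = 60.0, lp_hz: float = 1.0,
                               downsample: int = 140) -> float:
    """Slope of the slow photobleach phase on log10-log10 axes.

    The trace is zero-phase low-passed at ``lp_hz``, decimated ``downsample``
    times, the first ``skip_s`` seconds discarded, and a straight line fitted
    to log10(F) vs log10(t).  For ``F ∝ t^s`` the return value is ``s``.
    """
    low = zero_phase_filter(ts, "butterworth", "lowpass", 3, lp_hz)
    vals = low.values[::downsample]
    times = low.times[::downsample]
    keep = times > skip_s
    if keep.sum() < 4:
        raise ValueError("trace too short after skip_s for a power-law fit")
    vals, times = vals[keep], times[keep]
    if np.any(vals <= 0) or np.any(times <= 0):
        raise ValueError("nonpositive values after filtering; log10 undefined")
    slope, _ = np.polyfit(np.log10(times), np.log10(vals), 1)
    return float(slope)


# --------------------------------------------------------------------------
# ΔF/F₀ conventions

def dff_highpass(ts, hp_hz: float = 0.5):
    """%ΔF/F₀ with mean-signal F₀ after zero-phase high-pass drift removal.

    ``out = 100 · highpass(x) / mean(x)`` in %ΔF/F₀ units; the mean of the
    output is ~0 by construction.
    """
    f0 = float(np.nanmean(ts.values))
    if f0 <= 0:
        raise ValueError("mean fluorescence must be positive for %dF/F")
    hp = zero_phase_filter(ts, "butterworth", "highpass", 2, hp_hz)
    return ts.copy(values=100.0 * hp.values / f0, units="%dF/F0")


def dff_polynomial(ts, exclude_mask: np.ndarray | None = None, degree: int = 3,
                   peak_sd: float = 2.0):
    """Polynomial-baseline −ΔF/F for resonant-scanning recordings.

    A polynomial of ``degree`` is fit to frames not excluded by
    ``exclude_mask`` (e.g. running frames); frames whose residual exceeds
    ``peak_sd`` standard deviations are dropped and the polynomial refit once.
    Returns ``negdff = max(dff) − dff`` (so depolarization — a fluorescence
    dip of a negative-going indicator — is positive, with exact minimum 0)
    and the baseline F₀ as a second series.
    """
    y = ts.values.astype(float)
    n = y.size
    include = ~np.isnan(y)
    if exclude_mask is not None:
        include &= ~np.asarray(exclude_mask, dtype=bool)
    if include.sum() < degree + 2:
        raise ValueError("not enough included frames for the baseline fit")
    t = np.arange(n, dtype=float)

    coef = np.polyfit(t[include], y[include], degree)
    resid = y - np.polyval(coef, t)
    sd = np.std(resid[include])
    refined = include & ~(resid > peak_sd * sd)  # drop bright peaks only
    if refined.sum() >= degree + 2:
        coef = np.polyfit(t[refined], y[refined], degree)

    f0 = np.polyval(coef, t)
    if np.any(f0 <= 0):
        raise ValueError("polynomial baseline non-positive; dF/F undefined")
    dff = (y - f0) / f0
    negdff = np.nanmax(dff) - dff
    return ts.copy(values=negdff, units="-dF/F"), ts.copy(values=f0, units=ts.units)


def dff_rolling_percentile(ts, pct: float = 5.0, window_min: float = 20.0,
                           lp_hz: float = 5.0, invert: bool = True):
    """ΔF/F₀ against a rolling-percentile baseline.

    Steps, in order: invert (reflect about the trace mean, so dips of a
    negative-going indicator become positive-going responses while the trace
    stays positive), zero-phase Hamming low-pass at ``lp_hz``, then normalize
    ``(y − F₀)/F₀`` where F₀ is the centered rolling ``pct``-th percentile
    over a ``window_min``-minute window (truncated at the edges; windows
    longer than the trace fall back to a single global percentile).
    """
    y = ts.values.astype(float)
    if invert:
        y = 2.0 * np.nanmean(y) - y
    work = ts.copy(values=y)
    if lp_hz < 0.45 * ts.rate_hz:
        ntaps = min((int(2 * ts.rate_hz / lp_hz) | 1), (work.values.size // 3) | 1)
        ntaps = max(ntaps, 5)
        low = zero_phase_filter(work, "hamming_fir", "lowpass", ntaps, lp_hz)
    else:
        low = work    # cutoff at/above Nyquist: low-pass is a no-op

    win = int(round(window_min * 60.0 * ts.rate_hz))
    series = pd.Series(low.values)
    if win >= series.size:
        f0 = np.full(series.size, np.nanpercentile(low.values, pct))
    else:
        f0 = series.rolling(win, center=True, min_periods=max(2, win // 10)) \
                   .quantile(pct / 100.0).to_numpy()
        f0 = pd.Series(f0).bfill().ffill().to_numpy()
    if np.any(f0 <= 0):
        raise ValueError("rolling-percentile baseline non-positive")
    return ts.copy(values=(low.values - f0) / f0, units="dF/F0")
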