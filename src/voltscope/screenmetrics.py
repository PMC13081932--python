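"""High-throughput screening quantification and compound metrics.

Per screening stack (green GEVI channel, red reference channel):
background subtraction from the intensity-histogram mode, a membrane-pixel
mask from the first-frame composite, relative brightness (green/red over the
first 20 frames), photostability as the normalized area under the
F(t)/F(0) curve, and peak response amplitudes to field stimulation,
hierarchically averaged FOV → well → variant.  Variants are ranked by

    detectability index  = response × √brightness
    detectability budget = index × √photostability

plus the quadratic illumination-power correction used for excitation
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScreenResult:
    response_amplitude: float
    relative_brightness: float
    photostability: float

    def __post_init__(self) -> None:
        if min(self.response_amplitude, self.relative_brightness, self.photostability) < 0:
            raise ValueError("screen metrics must be nonnegative")
        # identities asserted on every construction
        self.detectability_index = self.response_amplitude * np.sqrt(self.relative_brightness)
        self.detectability_budget = self.detectability_index * np.sqrt(self.photostability)


def _histogram_mode(frame: np.ndarray, bins: int = 256) -> float:
    counts, edges = np.histogram(frame.ravel(), bins=bins)
    i = int(np.argmax(counts))
    return 0.5 * (edges[i] + edges[i + 1])


def segment_and_extract(green_stack: np.ndarray, red_stack: np.ndarray,
                        mask_percentile: float = 90.0,
                        saturation_level: float | None = None):
    """Background-subtracted per-frame mean traces over a membrane mask.

    Background per channel is the mode of a 256-bin intensity histogram of
    the first frame.  The mask thresholds the first-frame composite
    (mean of both background-subtracted channels) at ``mask_percentile`` of
    its non-saturated pixels; saturated pixels are excluded.
    """
    g = np.asarray(green_stack, dtype=float)
    r = np.asarray(red_stack, dtype=float)
    if g.shape != r.shape or g.ndim != 3:
        raise ValueError("stacks must be co-registered (frames, h, w) arrays")

    bg_g = _histogram_mode(g[0])
    bg_r = _histogram_mode(r[0])
    g0 = g[0] - bg_g
    r0 = r[0] - bg_r

    if saturation_level is None:
        saturation_level = max(g.max(), r.max())
        saturated = (g[0] >= saturation_level) | (r[0] >= saturation_level)
        if saturated.all():
            saturated = np.zeros_like(saturated)
    else:
        saturated = (g[0] >= saturation_level) | (r[0] >= saturation_level)

    composite = 0.5 * (g0 + r0)
    eligible = composite[~saturated]
    if eligible.size == 0:
        raise ValueError("all pixels saturated")
    thresh = np.percentile(eligible, mask_percentile)
    mask = (composite > thresh) & ~saturated
    if not mask.any():
        raise ValueError("empty membrane mask")

    green_trace = (g - bg_g)[:, mask].mean(axis=1)
    red_trace = (r - bg_r)[:, mask].mean(axis=1)
    return green_trace, red_trace, mask, (bg_g, bg_r)


def relative_brightness(green_trace, red_trace, n_frames: int = 20) -> float:
    """Mean of the first ``n_frames`` green samples over the red mean."""
    g = np.asarray(green_trace, dtype=float)
    r = np.asarray(red_trace, dtype=float)
    if g.size < n_frames or r.size < n_frames:
        raise ValueError(f"need at least {n_frames} frames per channel")
    red_mean = r[:n_frames].mean()
    if red_mean <= 0:
        raise ValueError("non-positive red reference mean")
    return float(g[:n_frames].mean() / red_mean)


def photostability_auc(trace, rate_hz: float = 1.0) -> float:
    """Trapezoidal area under F(t)/F(0) over the recording (seconds).

    Across a comparison set, divide each AUC by the set maximum with
    :func:`normalize_aucs` to obtain photostability in (0, 1].
    """
    f = np.asarray(trace, dtype=float)
    if f[0] <= 0:
        raise ValueError("F(0) must be positive")
    t = np.arange(f.size) / rate_hz
    return float(np.trapezoid(f / f[0], t))


def normalize_aucs(aucs) -> np.ndarray:
    a = np.asarray(aucs, dtype=float)
    if np.any(a <= 0):
        raise ValueError("AUCs must be positive")
    return a / a.max()


def response_amplitude(trace, rate_hz: float, stim_onsets_s,
                       window_s: float = 0.1, f0: float | None = None) -> np.ndarray:
    """Per-stimulation peak |ΔF/F₀| within ``window_s`` after each onset.

    ``trace`` must be photobleach-corrected; onsets outside the trace are
    skipped.  F₀ defaults to the pre-first-stimulus mean.
    """
    f = np.asarray(trace, dtype=float)
    onsets = np.asarray(stim_onsets_s, dtype=float)
    dur = f.size / rate_hz
    if f0 is None:
        first = int(onsets.min() * rate_hz) if onsets.size else f.size
        f0 = f[:max(first, 1)].mean()
    if f0 <= 0:
        raise ValueError("non-positive baseline")
    amps = []
    for t in onsets:
        if t < 0 or t >= dur:
            continue
        i0 = int(t * rate_hz)
        i1 = min(int((t + window_s) * rate_hz) + 1, f.size)
        dff = (f[i0:i1] - f0) / f0
        amps.append(np.abs(dff).max())
    return np.asarray(amps)


def average_hierarchy(per_fov: dict) -> dict:
    """FOV → well → variant averaging of response amplitudes.

    ``per_fov`` maps (variant, well, fov) -> amplitude; returns
    variant -> mean over its wells of each well's FOV mean.
    """
    wells: dict = {}
    for (variant, well, _fov), amp in per_fov.items():
        wells.setdefault((variant, well), []).append(amp)
    variants: dict = {}
    for (variant, _well), amps in wells.items():
        variants.setdefault(variant, []).append(float(np.mean(amps)))
    return {v: float(np.mean(w)) for v, w in variants.items()}


def compound_metrics(response: float, rel_brightness: float,
                     photostability: float) -> tuple[float, float]:
    """(detectability index, detectability budget)."""
    res = ScreenResult(response, rel_brightness, photostability)
    return res.detectability_index, res.detectability_budget


def power_correct(fluorescence, measured_power_mw: float,
                  target_power_mw: float) -> np.ndarray:
    """Quadratic two-photon power correction: F × (target/measured)²."""
    if measured_power_mw <= 0 or target_power_mw <= 0:
        raise ValueError("powers must be positive")
    return np.asarray(fluorescence, dtype=float) * (target_power_mw / measured_power_mw) ** 2
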