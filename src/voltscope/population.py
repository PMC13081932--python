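"""Population-level subthreshold analysis for trial-structured recordings.

Implements the analysis chain for megahertz line-scan (FACED-style)
population voltage imaging with drifting-grating stimuli:

1. neuropil mask growth and weighted subtraction,
2. trialization of −ΔF/F responses against a per-presentation blank baseline,
3. visually-evoked (VE) and orientation-selective (OS) cell classification,
4. bimodal-Gaussian direction tuning fits and the global orientation
   selectivity index (gOSI),
5. pairwise Pearson correlations of subthreshold traces.

Direction convention: the 8 grating directions 0°–315° in 45° steps; the
angular distance ``ang(θ)`` wraps to [0°, 180°] so that opposite drift
directions of the same orientation are 180° apart in the tuning model but
identical for gOSI (which uses e^{i2θ}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .signal_ops import zero_phase_filter
from .timeseries import TimeSeries

DIRECTIONS_DEG = np.arange(0, 360, 45)


# --------------------------------------------------------------------------
# Tuning model

def ang(theta_deg):
    """Angular distance wrapped to the interval [0°, 180°]."""
    a = np.abs(np.asarray(theta_deg, dtype=float)) % 360.0
    return np.minimum(a, 360.0 - a)


def bimodal_gaussian(theta_deg, c_offset, c_pref, c_oppo, theta_pref_deg, sigma_deg):
    """Direction tuning: offset plus Gaussians at θ_pref and θ_pref+180°."""
    d1 = ang(np.asarray(theta_deg, dtype=float) - theta_pref_deg)
    d2 = ang(np.asarray(theta_deg, dtype=float) - theta_pref_deg + 180.0)
    return (c_offset
            + c_pref * np.exp(-d1 ** 2 / (2.0 * sigma_deg ** 2))
            + c_oppo * np.exp(-d2 ** 2 / (2.0 * sigma_deg ** 2)))


@dataclass
class TuningFit:
    c_offset: float
    c_pref: float
    c_oppo: float
    theta_pref_deg: float
    sigma_deg: float
    gosi: float = np.nan
    rss: float = np.inf
    degenerate: bool = False

    def predict(self, theta_deg):
        return bimodal_gaussian(theta_deg, self.c_offset, self.c_pref,
                                self.c_oppo, self.theta_pref_deg, self.sigma_deg)


def fit_tuning(responses, directions_deg=DIRECTIONS_DEG) -> TuningFit:
    """Least-squares bimodal-Gaussian fit of per-direction mean responses.

    Deterministic multi-start over θ_pref at each stimulus direction; the
    best-RSS polished fit wins.  All-equal responses yield a degenerate flat
    fit with zero Gaussian amplitudes.
    """
    r = np.asarray(responses, dtype=float)
    th = np.asarray(directions_deg, dtype=float)
    if r.size != th.size:
        raise ValueError("responses and directions must align")

    if np.ptp(r) < 1e-12 * max(1.0, np.abs(r).max()):
        fit = TuningFit(c_offset=float(r.mean()), c_pref=0.0, c_oppo=0.0,
                        theta_pref_deg=0.0, sigma_deg=45.0, rss=0.0, degenerate=True)
        fit.gosi = compute_gosi(r, th)
        return fit

    best = None
    for th0 in th:
        p0 = [r.min(), max(r.max() - r.min(), 1e-6), 0.5 * (r.max() - r.min()), th0, 30.0]

        def resid(p):
            return bimodal_gaussian(th, p[0], p[1], p[2], p[3], p[4]) - r

        sol = optimize.least_squares(
            resid, p0, bounds=([-np.inf, 0.0, 0.0, -360.0, 5.0],
                               [np.inf, np.inf, np.inf, 720.0, 180.0]),
            xtol=1e-14, ftol=1e-14, max_nfev=5000)
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol.x)

    rss, p = best
    c_pref, c_oppo, theta = float(p[1]), float(p[2]), float(p[3] % 360.0)
    # the model is symmetric under (theta+180, swap lobes): canonicalize so
    # the preferred direction carries the larger lobe
    if c_oppo > c_pref:
        c_pref, c_oppo = c_oppo, c_pref
        theta = (theta + 180.0) % 360.0
    fit = TuningFit(c_offset=float(p[0]), c_pref=c_pref, c_oppo=c_oppo,
                    theta_pref_deg=theta, sigma_deg=float(p[4]), rss=rss)
    fit.gosi = compute_gosi(r, th)
    return fit


def compute_gosi(responses, directions_deg=DIRECTIONS_DEG) -> float:
    """Global orientation-selectivity index |Σ R e^{i2θ}| / Σ R.

    Negative mean responses are clipped to zero first so the index stays in
    [0, 1]; an all-zero response vector yields NaN (undefined).
    """
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    total = r.sum()
    if total <= 0:
        return float("nan")
    return float(np.abs(np.sum(r * np.exp(2j * th))) / total)


# --------------------------------------------------------------------------
# Neuropil

def grow_neuropil_mask(roi_masks: list[np.ndarray], roi_index: int,
                       intensity_image: np.ndarray, max_pixels: int = 300,
                       top_intensity_frac: float = 0.04) -> np.ndarray:
    """Grow a neuropil ring around one ROI by repeated 8-connected dilation.

    Pixels of any ROI and the brightest ``top_intensity_frac`` of the
    field-of-view (puncta) are never included.  Rings are accumulated until
    the mask exceeds ``max_pixels``; the final ring is kept whole.
    Returns a boolean mask (empty, with a warning-flag of all-False, when the
    ROI is fully surrounded by exclusions).
    """
    roi = np.asarray(roi_masks[roi_index], dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    excluded = np.zeros_like(roi)
    for m in roi_masks:
        excluded |= np.asarray(m, dtype=bool)
    thresh = np.quantile(intensity_image, 1.0 - top_intensity_frac)
    excluded |= intensity_image > thresh

    structure = np.ones((3, 3), dtype=bool)  # 8-connected
    mask = np.zeros_like(roi)
    frontier = roi.copy()
    # Bounded by image size: each iteration grows the frontier by one pixel.
    for _ in range(max(roi.shape)):
        dilated = ndimage.binary_dilation(frontier, structure=structure)
        ring = dilated & ~frontier & ~excluded
        frontier = dilated
        if not ring.any() and frontier.all():
            break
        mask |= ring
        if mask.sum() > max_pixels:
            break
    return mask


def neuropil_subtract(f_raw: TimeSeries, f_neuropil: TimeSeries, weight: float = 0.7):
    """``F_ROI = F_raw − weight·F_neuropil``; contaminated ROIs are excluded.

    Returns ``(TimeSeries, excluded: bool)``; exclusion (mean neuropil
    fluorescence above 1.1× the mean raw fluorescence) returns the input
    unchanged with the flag set.
    """
    if len(f_raw) != len(f_neuropil):
        raise ValueError("raw and neuropil traces must have equal length")
    if np.nanmean(f_neuropil.values) > 1.1 * np.nanmean(f_raw.values):
        return f_raw.copy(), True
    return f_raw.copy(values=f_raw.values - weight * f_neuropil.values), False


# --------------------------------------------------------------------------
# Trialization

def trialize_responses(froi: TimeSeries, schedule: pd.DataFrame,
                       baseline_window=(0.3, 0.5), stim_s: float = 0.5,
                       post_s: float = 0.3, lp_hz: float = 12.0,
                       lp_order: int = 3) -> pd.DataFrame:
    """Per-presentation subthreshold responses R from a corrected ROI trace.

    ``schedule`` columns: blank_start_s, stim_start_s, direction_deg.  For
    each presentation the baseline F is the mean raw signal over
    [blank+0.3 s, blank+0.5 s]; the −ΔF/F trace (per-presentation baseline)
    is low-passed (3rd-order 12-Hz Butterworth, zero phase) and
    R = its mean over the 0.5-s stimulus plus the following 0.3 s.  The mean
    over the final 0.2 s of the preceding blank is stored for the VE test.

    Returns a table with columns presentation, direction_deg, R, blank_final.
    """
    req = {"blank_start_s", "stim_start_s", "direction_deg"}
    if not req.issubset(schedule.columns):
        raise ValueError(f"schedule must have columns {sorted(req)}")
    tmax = froi.t0_s + froi.duration_s
    if schedule["stim_start_s"].max() + stim_s + post_s > tmax + 1e-9:
        raise ValueError("stimulus schedule extends beyond the trace")

    # Build a full-length -dF/F trace using each presentation's own baseline
    # on its segment, then low-pass once.
    neg = np.zeros(len(froi))
    edges = list(schedule["blank_start_s"]) + [tmax]
    for i, row in enumerate(schedule.itertuples(index=False)):
        b = row.blank_start_s
        base = froi.slice_seconds(b + baseline_window[0], b + baseline_window[1]).mean()
        if base == 0:
            raise ValueError("zero baseline fluorescence")
        i0 = froi.index_at(edges[i])
        i1 = froi.index_at(edges[i + 1]) if i + 1 < len(edges) else len(froi)
        seg = froi.values[i0:i1]
        neg[i0:i1] = -(seg - base) / base

    neg_ts = TimeSeries(neg, froi.rate_hz, froi.t0_s, "-dF/F")
    low = zero_phase_filter(neg_ts, "butterworth", "lowpass", lp_order, lp_hz)

    rows = []
    for i, row in enumerate(schedule.itertuples(index=False)):
        s = row.stim_start_s
        r = low.slice_seconds(s, s + stim_s + post_s).mean()
        blank_final = low.slice_seconds(s - 0.2, s).mean()
        rows.append({"presentation": i, "direction_deg": float(row.direction_deg),
                     "R": float(r), "blank_final": float(blank_final)})
    return pd.DataFrame(rows)


def classify_cells(trial_tables: dict, alpha_family: float = 0.05,
                   alpha_os: float = 0.05) -> pd.DataFrame:
    """Visually-evoked (VE) and orientation-selective (OS) classification.

    Per cell, a one-sided paired t-test per direction compares R against the
    blank-final mean across trials; the cell is VE when any direction's p
    falls below ``alpha_family / n_directions`` (0.05/8 = 0.00625, the
    Bonferroni-corrected threshold).  OS is evaluated only for VE cells by a
    one-way ANOVA of R across directions at ``alpha_os``.

    ``trial_tables`` maps cell id -> trialized response table.
    """
    out = []
    for cell, table in trial_tables.items():
        dirs = np.sort(table["direction_deg"].unique())
        thresh = alpha_family / len(dirs)
        p_min, groups = np.inf, []
        enough = True
        for d in dirs:
            sub = table[table["direction_deg"] == d]
            if len(sub) < 2:
                enough = False
                break
            res = stats.ttest_rel(sub["R"], sub["blank_final"], alternative="greater")
            p_min = min(p_min, res.pvalue)
            groups.append(sub["R"].to_numpy())
        if not enough:
            out.append({"cell": cell, "ve": False, "os": False, "p_ve": np.nan,
                        "p_os": np.nan, "undefined": True})
            continue
        ve = bool(p_min < thresh)
        p_os = np.nan
        os_flag = False
        if ve:
            p_os = float(stats.f_oneway(*groups).pvalue)
            os_flag = bool(p_os < alpha_os)
        out.append({"cell": cell, "ve": ve, "os": os_flag, "p_ve": float(p_min),
                    "p_os": p_os, "undefined": False})
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Correlations

def pairwise_correlations(traces: np.ndarray):
    """Pearson correlation matrix across cells and its off-diagonal mean.

    ``traces`` is (n_cells, n_samples).  Zero-variance cells produce NaN
    rows/columns; the mean is taken over the n(n−1)/2 finite unordered pairs.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two equal-length traces")
    sd = x.std(axis=1)
    cc = np.full((x.shape[0], x.shape[0]), np.nan)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(x[ok])
        cc[np.ix_(ok, ok)] = sub
    np.fill_diagonal(cc, 1.0)
    iu = np.triu_indices(x.shape[0], k=1)
    off = cc[iu]
    mean_cc = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return cc, mean_cc
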