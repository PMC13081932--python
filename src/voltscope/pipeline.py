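"""Session manifests and end-to-end pipeline drivers.

A session manifest is a JSON file listing channels (path, role, rate, units,
animal/cell ids) plus configuration; :func:`run_pipeline` chains the module
operations for one acquisition scheme and writes a summary JSON.  All stages
are deterministic given manifest + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import population, pupilphase, ripples, signal_ops, spikes
from .timeseries import read_timeseries, write_timeseries

STAGES = ("ulove", "faced", "ripples", "pupil")

_STAGE_ROLES = {
    "ulove": {"dff"},
    "faced": {"dff", "schedule"},
    "ripples": {"lfp", "dff"},
    "pupil": {"pupil", "velocity", "dff"},
}


@dataclass
class Channel:
    path: str
    role: str
    rate_hz: float | None = None
    units: str = ""
    animal_id: str = "a0"
    cell_id: str | None = None


@dataclass
class SessionManifest:
    channels: list
    config: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "SessionManifest":
        with open(path) as fh:
            raw = json.load(fh)
        channels = [Channel(**c) for c in raw["channels"]]
        return cls(channels=channels, config=raw.get("config", {}),
                   seed=int(raw.get("seed", 0)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"channels": [vars(c) for c in self.channels],
                       "config": self.config, "seed": self.seed}, fh, indent=1)

    def roles(self) -> set:
        return {c.role for c in self.channels}

    def by_role(self, role: str) -> list:
        return [c for c in self.channels if c.role == role]

    def validate(self, stage: str, base: Path) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        missing = _STAGE_ROLES[stage] - self.roles()
        if missing:
            raise ValueError(f"stage {stage!r} needs channel roles {sorted(missing)}")
        for c in self.channels:
            if not (base / c.path).exists():
                raise FileNotFoundError(f"channel file {c.path} not found")


def _summary_hash(summary: dict) -> str:
    blob = json.dumps(summary, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(manifest: SessionManifest, stage: str, out_dir, base_dir=".") -> dict:
    """Run one figure-level analysis stage and write ``summary.json``.

    ulove: photobleach correction, %ΔF/F, spike detection, waveform and
    subthreshold metrics, power-law slope.
    faced: trialization, VE/OS classification, tuning fits, gOSI, pairwise
    correlations (expects neuropil-corrected per-cell traces).
    ripples: ripple detection, onset clustering, single-inclusion peri-event
    average and peak/trough quantification.
    pupil: behavioral segmentation, pupil phase, ΔF/F and 2–10 Hz amplitude
    phase profiles.
    """
    base = Path(base_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.validate(stage, base)
    cfg = manifest.config

    summary: dict = {"stage": stage, "seed": manifest.seed}

    if stage == "ulove":
        ts = read_timeseries(base / manifest.by_role("dff")[0].path)
        corrected, fit = signal_ops.correct_photobleach_biexp(ts)
        dff = signal_ops.dff_highpass(corrected)
        dep = dff.copy(values=-dff.values)  # depolarization-positive
        det = spikes.detect_spikes(dep, z_thresh=cfg.get("z_thresh", 3.0))
        wf = spikes.spike_waveform_metrics(dep, det.onset_times_s)
        sub = spikes.subthreshold_summary(dep, det.onset_times_s, wf.amplitude_pct)
        try:
            slope = signal_ops.slow_bleach_powerlaw_slope(ts)
        except ValueError:
            slope = float("nan")
        summary.update({
            "n_spikes": int(det.n_spikes),
            "spike_amplitude_pct": wf.amplitude_pct,
            "spike_fwhm_ms": wf.fwhm_ms,
            "subthreshold_fluctuation_pct": sub.fluctuation_pct,
            "dynamic_range_pct": sub.dynamic_range_pct,
            "powerlaw_slope": slope,
            "bleach_tau_fast_s": fit.tau_s,
        })

    elif stage == "faced":
        import pandas as pd
        sched = pd.read_csv(base / manifest.by_role("schedule")[0].path, sep="\t")
        tables = {}
        traces = []
        for c in manifest.by_role("dff"):
            ts = read_timeseries(base / c.path)
            tables[c.cell_id or c.path] = population.trialize_responses(ts, sched)
            traces.append(ts.values)
        flags = population.classify_cells(tables, cfg.get("alpha_family", 0.05))
        fits = {}
        for cell, table in tables.items():
            means = table.groupby("direction_deg")["R"].mean()
            fits[cell] = population.fit_tuning(means.to_numpy(), means.index.to_numpy())
        _, mean_cc = population.pairwise_correlations(np.asarray(traces))
        summary.update({
            "n_cells": len(tables),
            "n_ve": int(flags["ve"].sum()),
            "n_os": int(flags["os"].sum()),
            "mean_gosi": float(np.nanmean([f.gosi for f in fits.values()])),
            "mean_pairwise_cc": mean_cc,
        })

    elif stage == "ripples":
        lfp = read_timeseries(base / manifest.by_role("lfp")[0].path)
        events = ripples.detect_ripples(lfp, thresh_sd=cfg.get("thresh_sd", 3.0))
        clustered = ripples.cluster_onsets(events)
        cells, animals = [], []
        for c in manifest.by_role("dff"):
            cells.append(read_timeseries(base / c.path))
            animals.append(c.animal_id)
        result = ripples.peri_event_average(cells, animals, clustered.representatives_s)
        quant = ripples.quantify_event_response(result)
        summary.update({
            "n_events": int(len(events.onset_times_s)),
            "n_representatives": int(clustered.representatives_s.size),
            "peak_time_ms": quant["peak_time_s"] * 1e3,
            "trough_time_ms": quant["trough_time_s"] * 1e3,
            "p_peak": quant["p_peak"], "p_trough": quant["p_trough"],
        })

    elif stage == "pupil":
        pupil = read_timeseries(base / manifest.by_role("pupil")[0].path)
        vel = read_timeseries(base / manifest.by_role("velocity")[0].path)
        dff = read_timeseries(base / manifest.by_role("dff")[0].path)
        running = pupilphase.detect_running(vel)
        segments = pupilphase.detect_pupil_periods(pupil, running)
        phase = pupilphase.pupil_phase(pupil)
        amp = pupilphase.band_amplitude_profile(dff)
        profile = pupilphase.phase_bin(amp, phase, segments)
        summary.update({
            "n_running_bouts": len(running),
            "n_valid_periods": len(segments.valid_periods),
            "profile_peak_phase_rad": float(profile.bin_centers[np.nanargmax(profile.mean)]),
            "profile_range": float(np.nanmax(profile.mean) - np.nanmin(profile.mean)),
        })

    summary["config_hash"] = _summary_hash({"config": cfg, "seed": manifest.seed})
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
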