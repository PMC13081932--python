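"""Uniformly sampled, NaN-aware time series container.

All pipeline stages exchange :class:`TimeSeries` objects: a 1-D value array
with a sampling rate (Hz), a start time (s) and a units label.  Sample ``i``
sits at ``t0_s + i / rate_hz``.  Missing samples (eye blinks, dropped frames)
are encoded as NaN in ``values``; ``nan_mask`` exposes them as a boolean
array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class TimeSeries:
    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("TimeSeries needs at least one sample")
        if not self.rate_hz > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.rate_hz

    @property
    def nan_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self, values: np.ndarray | None = None, units: str | None = None) -> "TimeSeries":
        return TimeSeries(
            values=self.values.copy() if values is None else np.asarray(values, dtype=float),
            rate_hz=self.rate_hz,
            t0_s=self.t0_s,
            units=self.units if units is None else units,
        )

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for time ``t_s`` (clipped to valid range)."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.values.size - 1)

    def slice_seconds(self, start_s: float, stop_s: float) -> np.ndarray:
        """Values in the half-open window [start_s, stop_s)."""
        i0 = int(np.ceil((start_s - self.t0_s) * self.rate_hz - 1e-9))
        i1 = int(np.ceil((stop_s - self.t0_s) * self.rate_hz - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.values.size)
        return self.values[i0:i1]


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write a two-column delimited text file plus a JSON sidecar.

    The text file has a header line ``time_s\\tvalue`` and one row per
    sample; NaN samples are written as the token ``nan``.  The sidecar
    ``<path>.json`` records rate, start time and units so the round trip is
    lossless.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s\tvalue\n")
        for t, v in zip(ts.times, ts.values):
            fh.write(f"{t:.9g}\t{v:.9g}\n")
    sidecar = {"rate_hz": ts.rate_hz, "t0_s": ts.t0_s, "units": ts.units}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a delimited-text trace written by :func:`write_timeseries`.

    Raises ``FileNotFoundError`` if the sidecar is missing and ``ValueError``
    (with line number) on a malformed row.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path} (need rate_hz)")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if "rate_hz" not in meta:
        raise ValueError(f"sidecar {sidecar_path} lacks rate_hz")
    values = []
    with open(path) as fh:
        header = fh.readline()
        if "value" not in header:
            raise ValueError(f"{path}:1: malformed header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value {parts[1]!r}") from exc
    return TimeSeries(
        values=np.asarray(values),
        rate_hz=float(meta["rate_hz"]),
        t0_s=float(meta.get("t0_s", 0.0)),
        units=str(meta.get("units", "")),
    )
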