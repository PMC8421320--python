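"""Time-series container for dynamic PET/MRI region curves.

A :class:`SampledCurve` holds one region's measurement versus time: a PET
time-activity curve (kBq/mL at frame midpoints), a gadolinium concentration
curve (mmol/L), or a raw MRI signal-intensity curve (arbitrary units).
Curves serialize to a two-column CSV (time_s, value) with a JSON sidecar
carrying the unit tag and, for PET, the frame durations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

VALID_UNITS = ("kBq/mL", "mmol/L", "a.u.")


class CurveError(ValueError):
    """Invalid curve construction or incompatible curve operation."""


@dataclass(frozen=True)
class SampledCurve:
    """Measurement samples for one region.

    Parameters
    ----------
    times
        Seconds from injection (frame midpoints for PET), strictly increasing.
    values
        Measurement at each time point; must be finite.
    unit_tag
        One of ``kBq/mL`` (PET activity), ``mmol/L`` (Gd concentration),
        ``a.u.`` (raw MRI signal).
    frame_durations
        Optional per-frame durations in seconds (PET only); positive, same
        length as ``times``.
    """

    times: np.ndarray
    values: np.ndarray
    unit_tag: str = "a.u."
    frame_durations: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise CurveError("times and values must be 1-D of equal length")
        if times.size < 2:
            raise CurveError("a curve needs at least two samples")
        if not np.all(np.diff(times) > 0):
            raise CurveError("times must be strictly increasing")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
            raise CurveError("times and values must be finite")
        if self.unit_tag not in VALID_UNITS:
            raise CurveError(f"unknown unit_tag {self.unit_tag!r}; expected one of {VALID_UNITS}")
        if self.frame_durations is not None:
            fd = np.asarray(self.frame_durations, dtype=float)
            object.__setattr__(self, "frame_durations", fd)
            if fd.shape != times.shape:
                raise CurveError("frame_durations must match times in length")
            if not np.all(fd > 0):
                raise CurveError("frame_durations must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray) -> "SampledCurve":
        """Return a copy with the same time grid and new values."""
        return SampledCurve(self.times.copy(), np.asarray(values, dtype=float),
                            self.unit_tag, None if self.frame_durations is None
                            else self.frame_durations.copy())

    def interp(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``times``; error outside support."""
        times = np.asarray(times, dtype=float)
        if times.min() < self.times[0] - 1e-9 or times.max() > self.times[-1] + 1e-9:
            raise CurveError(
                f"requested times [{times.min():g}, {times.max():g}] s outside curve "
                f"support [{self.times[0]:g}, {self.times[-1]:g}] s")
        return np.interp(times, self.times, self.values)

    # --- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.csv`` (time_s,value) and ``<path>.json`` sidecar."""
        path = Path(path)
        stem = path.with_suffix("") if path.suffix == ".csv" else path
        arr = np.column_stack([self.times, self.values])
        np.savetxt(stem.with_suffix(".csv"), arr, delimiter=",",
                   header="time_s,value", comments="", fmt="%.10g")
        sidecar = {"unit_tag": self.unit_tag,
                   "frame_durations": None if self.frame_durations is None
                   else self.frame_durations.tolist()}
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SampledCurve":
        path = Path(path)
        stem = path.with_suffix("") if path.suffix in (".csv", ".json") else path
        arr = np.loadtxt(stem.with_suffix(".csv"), delimiter=",", skiprows=1, ndmin=2)
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        fd = sidecar.get("frame_durations")
        return cls(arr[:, 0], arr[:, 1], sidecar.get("unit_tag", "a.u."),
                   None if fd is None else np.asarray(fd, dtype=float))
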