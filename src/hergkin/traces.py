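"""Current traces and their delimited-text serialization.

A trace is a time series of (simulated or measured) current with the
segment structure of the protocol that elicited it and the recording
conditions.  The on-disk format is two-column delimited text with a
commented header block, chosen over binary for diffability::

    # hergkin-trace v1
    # key = value        (conditions, protocol name, sweep value, ...)
    # segment_bounds_ms = 0,1000,2000
    # columns = time_ms current
    0.0 0.0
    ...
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

_MAGIC = "# hergkin-trace v1"


@dataclass
class CurrentTrace:
    """Time series of current with segment annotations.

    Attributes
    ----------
    time : ndarray, ms, strictly increasing.
    current : ndarray, pA/pF (or normalized units).
    segment_bounds : start times (ms) of each segment plus the final
        end time; segment k spans [bounds[k], bounds[k+1]].
    segment_voltages : command voltage of each segment, mV.
    sweep_value : the swept quantity of this sweep (mV or ms).
    conditions : free-form recording conditions (T, Ko, isoform, ...).
    open_prob : optional open-state occupancy alongside ``current``.
    occupancy : optional (n_samples, n_states) full state occupancy.
    """

    time: np.ndarray
    current: np.ndarray
    segment_bounds: np.ndarray
    segment_voltages: np.ndarray
    sweep_value: float = float("nan")
    conditions: dict = field(default_factory=dict)
    open_prob: np.ndarray | None = None
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.segment_bounds = np.asarray(self.segment_bounds, dtype=float)
        self.segment_voltages = np.asarray(self.segment_voltages, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValidationError("time and current must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if self.segment_bounds.size and (
            self.segment_bounds[0] < self.time[0] - 1e-9
            or self.segment_bounds[-1] > self.time[-1] + 1e-9
        ):
            raise ValidationError("segment boundaries outside trace time range")

    @property
    def n_segments(self) -> int:
        return max(self.segment_bounds.size - 1, 0)

    def segment_slice(self, index: int) -> slice:
        """Sample index range of segment ``index``.

        A sample at a voltage-step boundary belongs to the preceding
        segment (segments own (t0, t1]; the first segment owns its
        start too).
        """
        if not 0 <= index < self.n_segments:
            raise ValidationError(f"segment index {index} out of range")
        t0, t1 = self.segment_bounds[index], self.segment_bounds[index + 1]
        eps = -1e-9 if index == 0 else 1e-9
        i0 = int(np.searchsorted(self.time, t0 + eps))
        i1 = int(np.searchsorted(self.time, t1 + 1e-9))
        return slice(i0, i1)

    def segment_time(self, index: int) -> np.ndarray:
        """Times of segment ``index`` relative to its start."""
        sl = self.segment_slice(index)
        return self.time[sl] - self.segment_bounds[index]


def export_trace(trace: CurrentTrace, path: str | Path, precision: int = 17) -> None:
    """Write a trace as commented-header delimited text."""
    path = Path(path)
    lines = [_MAGIC]
    for key, value in sorted(trace.conditions.items()):
        lines.append(f"# {key} = {value!r}")
    lines.append(f"# sweep_value = {trace.sweep_value!r}")
    bounds = ",".join(f"{b:.{precision}g}" for b in trace.segment_bounds)
    volts = ",".join(f"{v:.{precision}g}" for v in trace.segment_voltages)
    lines.append(f"# segment_bounds_ms = {bounds}")
    lines.append(f"# segment_voltages_mV = {volts}")
    lines.append("# columns = time_ms current")
    fmt = f"%.{precision}g %.{precision}g"
    for t, i in zip(trace.time, trace.current):
        lines.append(fmt % (t, i))
    path.write_text("\n".join(lines) + "\n")


def import_trace(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`export_trace`.

    Raises
    ------
    ValidationError
        With line diagnostics for malformed files.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise ValidationError(f"{path}: missing '{_MAGIC}' header")
    conditions: dict = {}
    sweep_value = float("nan")
    bounds: np.ndarray | None = None
    volts: np.ndarray | None = None
    data = []
    for ln, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key, value = key.strip(), value.strip()
            if key == "segment_bounds_ms":
                bounds = np.array([float(x) for x in value.split(",") if x])
            elif key == "segment_voltages_mV":
                volts = np.array([float(x) for x in value.split(",") if x])
            elif key == "sweep_value":
                sweep_value = float(ast.literal_eval(value))
            elif key != "columns":
                try:
                    conditions[key] = ast.literal_eval(value)
                except (ValueError, SyntaxError):
                    conditions[key] = value
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(
                f"{path}:{ln}: expected 2 columns, got {len(parts)}"
            )
        try:
            data.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln}: {exc}") from None
    if not data:
        raise ValidationError(f"{path}: no data rows")
    arr = np.array(data)
    if bounds is None:
        bounds = np.array([arr[0, 0], arr[-1, 0]])
    if volts is None:
        volts = np.full(max(bounds.size - 1, 1), np.nan)
    return CurrentTrace(
        time=arr[:, 0], current=arr[:, 1],
        segment_bounds=bounds, segment_voltages=volts,
        sweep_value=sweep_value, conditions=conditions,
    )
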