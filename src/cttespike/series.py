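"""Event series container and plain-text / CSV I/O.

A point process (spike train) is represented simply by its sorted event
times.  Files are either newline-delimited floats (one event time per
line, ``#`` comments and blank lines ignored) or CSV with a ``time``
column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EventSeries", "read_event_series", "write_event_series"]


class ParseError(ValueError):
    """Raised when an event-time file cannot be parsed."""


@dataclass(frozen=True)
class EventSeries:
    """A single point process: strictly increasing, finite event times.

    Parameters
    ----------
    times
        Sorted event times, in arbitrary (but consistent) time units.
    label
        Optional process name, carried through for reporting.
    """

    times: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("event times must be a 1-d sequence")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("event times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        """Length of the recording, last event minus first event."""
        if len(self) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def shifted(self, offset: float) -> "EventSeries":
        """Return a copy with every event translated by ``offset``."""
        return EventSeries(self.times + offset, label=self.label)


def _ensure_strict(times: np.ndarray) -> np.ndarray:
    """Nudge duplicated times up by machine steps so order is strict."""
    times = np.sort(np.asarray(times, dtype=float))
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = np.nextafter(times[i - 1], np.inf)
    return times


def read_event_series(path: str | Path, fmt: str | None = None,
                      label: str = "") -> EventSeries:
    """Read a single event series from a text or CSV file.

    The format is inferred from the suffix unless ``fmt`` is given
    (``"txt"`` or ``"csv"``).  Times must already be sorted and strictly
    increasing; violations raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "txt"
    times: list[float] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "time" not in reader.fieldnames:
                raise ParseError(f"{path}: CSV file must have a 'time' column")
            for lineno, row in enumerate(reader, start=2):
                raw = (row["time"] or "").strip()
                if not raw:
                    continue
                try:
                    times.append(float(raw))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric time {raw!r}") from exc
    elif fmt == "txt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.split("#", 1)[0].strip()
                if not stripped:
                    continue
                try:
                    times.append(float(stripped))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric time {stripped!r}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")

    arr = np.asarray(times, dtype=float)
    if arr.size > 1:
        bad = np.nonzero(np.diff(arr) <= 0)[0]
        if bad.size:
            raise ParseError(
                f"{path}: times not strictly increasing at entry {bad[0] + 2} "
                f"({arr[bad[0] + 1]} follows {arr[bad[0]]})"
            )
    return EventSeries(arr, label=label or path.stem)


def write_event_series(series: EventSeries, path: str | Path,
                       fmt: str | None = None) -> None:
    """Write an event series as newline-delimited floats or CSV."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "txt"
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time"])
            for t in series.times:
                writer.writerow([repr(float(t))])
    elif fmt == "txt":
        with open(path, "w") as fh:
            for t in series.times:
                fh.write(f"{float(t)!r}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
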