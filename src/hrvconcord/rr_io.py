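"""Beat-series data model and plain-text readers/writers.

The central container is :class:`BeatSeries`: a strictly increasing axis of
beat times (milliseconds from recording start) together with the derived
beat-to-beat intervals (BBIs).  Two text formats are read:

* ``intervals_only`` — one BBI in ms per line; beat times are reconstructed
  from a zero origin by cumulative summation.
* ``time_interval_pairs`` — whitespace-separated ``time_ms interval_ms``
  per line; the time column is authoritative and BBIs are re-derived from it.

``#`` starts a comment; blank lines are ignored.  All times are milliseconds
internally.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyWarning, RRParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .hrv_metrics import HRVMetrics

__all__ = [
    "BeatSeries",
    "read_rr_text",
    "write_rr_text",
    "read_beat_annotations",
    "write_metrics_table",
    "read_metrics_table",
    "METRICS_COLUMNS",
]


@dataclass(frozen=True)
class BeatSeries:
    """One continuous recording: beat times (ms) and derived BBIs.

    Invariants enforced at construction: beat times strictly increasing and
    non-negative, at least two beats, hence every BBI positive.  BBI ``i``
    spans the half-open-on-the-left interval ``(beat_times[i],
    beat_times[i+1]]``.
    """

    beat_times: np.ndarray
    recording_id: str = "unnamed"

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=np.float64)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("no beats")
        if t.size < 2:
            raise ValidationError("a recording needs at least 2 beats (1 BBI)")
        if t[0] < 0:
            raise ValidationError("beat times must be non-negative")
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise ValidationError(
                f"beat times must be strictly increasing (violation at beat {bad + 1})"
            )
        object.__setattr__(self, "beat_times", t)

    @classmethod
    def from_bbis(
        cls, bbis: Sequence[float], t0_ms: float = 0.0, recording_id: str = "unnamed"
    ) -> "BeatSeries":
        """Build a series from intervals alone, placing the first beat at ``t0_ms``."""
        b = np.asarray(bbis, dtype=np.float64)
        if b.size == 0:
            raise ValidationError("no beats")
        if np.any(b <= 0):
            bad = int(np.flatnonzero(b <= 0)[0])
            raise ValidationError(f"non-positive interval at position {bad}")
        times = t0_ms + np.concatenate([[0.0], np.cumsum(b)])
        return cls(times, recording_id=recording_id)

    @property
    def bbis(self) -> np.ndarray:
        """Beat-to-beat intervals in ms; ``bbis[i] = beat_times[i+1] - beat_times[i]``."""
        return np.diff(self.beat_times)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def duration_ms(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    def __len__(self) -> int:
        return self.n_beats


def _parse_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            yield lineno, line.split()


def read_rr_text(
    path: str | Path,
    mode: str = "intervals_only",
    recording_id: str | None = None,
) -> BeatSeries:
    """Read a plain-text beat-interval file into a :class:`BeatSeries`.

    In ``intervals_only`` mode each line carries one BBI (ms) and the beat
    axis starts at 0.  In ``time_interval_pairs`` mode each line carries
    ``time_ms interval_ms``; the time column defines the axis and a
    :class:`ConsistencyWarning` is emitted when a stated interval disagrees
    with the interval derived from the times (derived values win).
    """
    if mode not in ("intervals_only", "time_interval_pairs"):
        raise ValueError(f"unknown mode: {mode!r}")
    rid = recording_id if recording_id is not None else Path(path).stem

    if mode == "intervals_only":
        bbis: list[float] = []
        for lineno, fields in _parse_lines(path):
            try:
                value = float(fields[0])
            except ValueError:
                raise RRParseError(f"not a number: {fields[0]!r}", lineno) from None
            if value <= 0:
                raise ValidationError(f"line {lineno}: non-positive interval {value}")
            bbis.append(value)
        if not bbis:
            raise ValidationError("no beats")
        return BeatSeries.from_bbis(bbis, recording_id=rid)

    times: list[float] = []
    stated: list[float] = []
    linenos: list[int] = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 2:
            raise RRParseError("expected 'time_ms interval_ms'", lineno)
        try:
            t, iv = float(fields[0]), float(fields[1])
        except ValueError:
            raise RRParseError(f"not a number: {' '.join(fields[:2])!r}", lineno) from None
        times.append(t)
        stated.append(iv)
        linenos.append(lineno)
    if not times:
        raise ValidationError("no beats")
    series = BeatSeries(np.asarray(times), recording_id=rid)
    # Stated interval on line i is checked against the derived interval that
    # ends at that line's beat time; the first line has no such interval.
    derived = series.bbis
    mismatched = [
        linenos[i]
        for i in range(1, len(stated))
        if abs(stated[i] - derived[i - 1]) > 0.5
    ]
    if mismatched:
        warnings.warn(
            f"stated intervals disagree with the time column on line(s) "
            f"{mismatched}; intervals derived from times are used",
            ConsistencyWarning,
            stacklevel=2,
        )
    return series


def write_rr_text(series: BeatSeries, path: str | Path, mode: str = "intervals_only") -> int:
    """Write a series to the RR text format; returns the number of lines written."""
    with open(path, "w", encoding="utf-8") as fh:
        if mode == "intervals_only":
            for b in series.bbis:
                fh.write(f"{float(b)!r}\n")
            return int(series.bbis.size)
        if mode == "time_interval_pairs":
            # one line per beat; the stated interval is the one ending at
            # that beat's time (the first line restates the first interval,
            # which the reader ignores)
            bbis = series.bbis
            fh.write(f"{float(series.beat_times[0])!r} {float(bbis[0])!r}\n")
            for i in range(1, series.n_beats):
                fh.write(f"{float(series.beat_times[i])!r} {float(bbis[i - 1])!r}\n")
            return series.n_beats
    raise ValueError(f"unknown mode: {mode!r}")


def read_beat_annotations(
    path: str | Path, sampling_hz: float, recording_id: str | None = None
) -> BeatSeries:
    """Optional reader for WFDB-style beat annotations exported as text.

    One integer sample index per line (``#`` comments allowed); beat times
    are ``index / sampling_hz * 1000`` ms.
    """
    if sampling_hz <= 0:
        raise ValidationError("sampling_hz must be positive")
    samples: list[float] = []
    for lineno, fields in _parse_lines(path):
        try:
            samples.append(float(fields[0]))
        except ValueError:
            raise RRParseError(f"not a number: {fields[0]!r}", lineno) from None
    if not samples:
        raise ValidationError("no beats")
    times = np.asarray(samples) / sampling_hz * 1000.0
    rid = recording_id if recording_id is not None else Path(path).stem
    return BeatSeries(times, recording_id=rid)


METRICS_COLUMNS = [
    "recording_id",
    "start_ms",
    "duration_s",
    "n_bbis",
    "rmssd_ms",
    "sdnn_ms",
    "lf_ms2",
    "hf_ms2",
]


def write_metrics_table(rows: Iterable["HRVMetrics"], path: str | Path) -> int:
    """Write HRV metric rows to CSV (UTF-8, ``.`` decimal); returns the row count.

    Missing frequency metrics (windows too short for spectral analysis) are
    written as empty cells, never as zeros.
    """
    rows = list(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METRICS_COLUMNS)
        for m in rows:
            writer.writerow(
                [
                    m.recording_id,
                    repr(float(m.start_ms)),
                    repr(float(m.duration_s)),
                    int(m.n_bbis),
                    _cell(m.rmssd_ms),
                    _cell(m.sdnn_ms),
                    _cell(m.lf_ms2),
                    _cell(m.hf_ms2),
                ]
            )
    return len(rows)


def _cell(value: float) -> str:
    return "" if value is None or np.isnan(value) else repr(float(value))


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV back; empty cells become NaN."""
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metrics table missing columns: {missing}")
    return df
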