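"""Artifact-free window scanning and one-segment-per-hour selection.

The study design needs, for every hour of recording, one 5-minute window in
which no BBI was flagged by artifact screening, plus the first minute of that
same window.  Candidate windows are evaluated on a start-time grid (default
one minute); a window is disqualified if *any* flagged BBI overlaps it, so a
surviving window's interior is guaranteed artifact-free.  Hourly selection is
greedy: take the first candidate, then repeatedly the earliest candidate
starting at least ``spacing_min`` minutes (start-to-start, inclusive) after
the last selected one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .preprocess import ArtifactMask
from .rr_io import BeatSeries

__all__ = ["Segment", "scan_clean_segments", "select_hourly", "extract_first_minute"]


@dataclass(frozen=True)
class Segment:
    """Half-open time window ``[start_ms, end_ms)`` into a parent recording.

    ``beat_indices`` are the indices of beats whose times fall in the window;
    the BBIs fully contained in the window are those between consecutive
    in-window beats.
    """

    parent: BeatSeries
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValidationError("segment window must have positive duration")
        if self.n_beats < 2:
            raise ValidationError(
                f"segment [{self.start_ms}, {self.end_ms}) contains "
                f"{self.n_beats} beat(s); at least 2 required"
            )

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0

    @property
    def beat_indices(self) -> np.ndarray:
        t = self.parent.beat_times
        i0 = int(np.searchsorted(t, self.start_ms, side="left"))
        i1 = int(np.searchsorted(t, self.end_ms, side="left"))
        return np.arange(i0, i1)

    @property
    def n_beats(self) -> int:
        t = self.parent.beat_times
        i0 = int(np.searchsorted(t, self.start_ms, side="left"))
        i1 = int(np.searchsorted(t, self.end_ms, side="left"))
        return i1 - i0

    @property
    def beat_times(self) -> np.ndarray:
        """Times (ms) of the beats inside the window."""
        return self.parent.beat_times[self.beat_indices]

    @property
    def bbi_indices(self) -> np.ndarray:
        """Indices into ``parent.bbis`` of BBIs fully contained in the window."""
        idx = self.beat_indices
        return idx[:-1]

    @property
    def bbis(self) -> np.ndarray:
        """BBIs (ms) fully contained in the window."""
        return self.parent.bbis[self.bbi_indices]


def scan_clean_segments(
    series: BeatSeries,
    mask: ArtifactMask,
    duration_s: float = 300.0,
    step_ms: float = 60_000.0,
    min_beats: int | None = None,
) -> list[Segment]:
    """All artifact-free candidate windows of ``duration_s`` on a start grid.

    A window qualifies iff no flagged BBI overlaps it (hence every BBI fully
    contained in it is clean) and it contains at least ``min_beats`` fully
    contained BBIs.  ``min_beats`` defaults to 0.4 per second of window
    (120 for 5 minutes), a guard against sparse or malformed masks.
    Windows never extend past the recording; no partial windows are emitted.
    """
    if len(mask) != series.bbis.size:
        raise ValidationError("mask is not aligned to the series")
    if min_beats is None:
        min_beats = int(0.4 * duration_s)
    dur_ms = duration_s * 1000.0
    t = series.beat_times
    t_begin, t_end = float(t[0]), float(t[-1])
    if dur_ms > t_end - t_begin:
        warnings.warn(
            f"window of {duration_s:g} s exceeds the {(t_end - t_begin) / 1000:g} s "
            "recording; no candidates",
            stacklevel=2,
        )
        return []

    art = mask.artifact_indices
    art_start = t[art]        # artifact BBI i spans (t[i], t[i+1]]
    art_end = t[art + 1]

    starts = np.arange(t_begin, t_end - dur_ms + 1e-9, step_ms)
    segments: list[Segment] = []
    for s in starts:
        e = s + dur_ms
        # any artifact BBI intersecting (s, e)?
        overlapping = np.count_nonzero((art_start < e) & (art_end > s))
        if overlapping:
            continue
        i0 = int(np.searchsorted(t, s, side="left"))
        i1 = int(np.searchsorted(t, e, side="left"))
        n_bbis = max(i1 - i0 - 1, 0)
        if n_bbis < min_beats:
            continue
        segments.append(Segment(series, float(s), float(e)))
    return segments


def select_hourly(candidates: list[Segment], spacing_min: float = 60.0) -> list[Segment]:
    """Greedy one-per-hour pick: first candidate, then the earliest starting
    at least ``spacing_min`` minutes after the last selected start (inclusive)."""
    spacing_ms = spacing_min * 60_000.0
    selected: list[Segment] = []
    for seg in candidates:
        if not selected or seg.start_ms >= selected[-1].start_ms + spacing_ms:
            selected.append(seg)
    return selected


def extract_first_minute(segment: Segment, short_duration_s: float = 60.0) -> Segment:
    """The opening ``short_duration_s`` sub-window of a 5-min segment.

    Shares the parent recording and the start time; cleanliness is inherited
    because any BBI overlapping the sub-window overlaps the full window.
    """
    if segment.duration_s <= short_duration_s:
        raise ValidationError("sub-window must be shorter than the segment")
    sub = Segment(segment.parent, segment.start_ms, segment.start_ms + short_duration_s * 1000.0)
    if sub.n_beats < 2:  # unreachable for clean windows (BBI <= 1500 ms)
        raise ValidationError("fewer than 2 beats in the first minute")
    return sub
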