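"""Artifact screening: label every BBI as clean, outlier, or ectopic.

Outliers are BBIs outside a physiological range (default 400-1500 ms, i.e.
heart rates above 150 or below 40 beats/min).  Ectopic beats are flagged by a
Malik-style relative-difference criterion: a BBI differing from the most
recent accepted (non-outlier, non-ectopic) BBI by more than a fraction of it
(default 20%).  This module only labels; it never removes intervals —
downstream segment selection keeps only windows in which nothing was flagged,
so no statistic is ever computed on an edited series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .rr_io import BeatSeries

__all__ = [
    "CLEAN",
    "OUTLIER",
    "ECTOPIC",
    "OutlierRule",
    "EctopicRule",
    "ArtifactMask",
    "detect_outliers",
    "detect_ectopic",
    "bbi_to_heart_rate",
    "build_mask",
]

CLEAN = "clean"
OUTLIER = "outlier"
ECTOPIC = "ectopic"


@dataclass(frozen=True)
class OutlierRule:
    """Acceptable BBI range in ms; bounds themselves are clean (inclusive)."""

    low_ms: float = 400.0
    high_ms: float = 1500.0

    def __post_init__(self) -> None:
        if not (0 < self.low_ms < self.high_ms):
            raise ValidationError("outlier rule requires 0 < low_ms < high_ms")


@dataclass(frozen=True)
class EctopicRule:
    """Relative-difference ectopy criterion against the last accepted BBI."""

    method: str = "malik_relative"
    rel_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.method != "malik_relative":
            raise ValidationError(f"unknown ectopic method: {self.method!r}")
        if not (0 < self.rel_threshold < 1):
            raise ValidationError("rel_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ArtifactMask:
    """Per-BBI labels aligned to ``BeatSeries.bbis``, plus the rules applied."""

    labels: np.ndarray
    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    ectopic_rule: EctopicRule = field(default_factory=EctopicRule)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        bad = set(labels) - {CLEAN, OUTLIER, ECTOPIC}
        if bad:
            raise ValidationError(f"unknown labels: {sorted(map(str, bad))}")
        object.__setattr__(self, "labels", labels)

    @property
    def is_clean(self) -> np.ndarray:
        return self.labels == CLEAN

    @property
    def artifact_indices(self) -> np.ndarray:
        """Indices of BBIs labelled outlier or ectopic, ascending."""
        return np.flatnonzero(~self.is_clean)

    def __len__(self) -> int:
        return int(self.labels.size)


def bbi_to_heart_rate(bbi_ms: float) -> float:
    """Heart rate (beats/min) equivalent of one BBI: 60000 / bbi.

    400 ms -> 150 BPM and 1500 ms -> 40 BPM, the heart-rate reading of the
    default outlier bounds.
    """
    if bbi_ms <= 0:
        raise ValidationError("bbi must be positive")
    return 60000.0 / float(bbi_ms)


def detect_outliers(series: BeatSeries, rule: OutlierRule | None = None) -> set[int]:
    """Indices of BBIs strictly outside ``[low_ms, high_ms]``."""
    rule = rule if rule is not None else OutlierRule()
    bbis = series.bbis
    out = np.flatnonzero((bbis < rule.low_ms) | (bbis > rule.high_ms))
    return set(map(int, out))


def detect_ectopic(
    series: BeatSeries,
    rule: EctopicRule | None = None,
    outlier_indices: set[int] | frozenset[int] | None = None,
) -> set[int]:
    """Indices of ectopic BBIs under the relative-difference criterion.

    BBI ``i`` (i >= 1) is ectopic iff it differs from the most recent
    accepted BBI (neither ectopic nor in ``outlier_indices``) by more than
    ``rel_threshold`` of that reference.  The first BBI is never ectopic; a
    BBI with no accepted predecessor is accepted as the new reference.
    """
    rule = rule if rule is not None else EctopicRule()
    outliers = outlier_indices if outlier_indices is not None else set()
    bbis = series.bbis
    if bbis.size < 2:
        warnings.warn("fewer than 2 BBIs: ectopic detection is a no-op", stacklevel=2)
        return set()
    ectopic: set[int] = set()
    ref: float | None = None if 0 in outliers else float(bbis[0])
    for i in range(1, bbis.size):
        if i in outliers:
            continue
        b = float(bbis[i])
        if ref is not None and abs(b - ref) > rule.rel_threshold * ref:
            ectopic.add(i)
        else:
            ref = b
    return ectopic


def build_mask(
    series: BeatSeries,
    outlier_rule: OutlierRule | None = None,
    ectopic_rule: EctopicRule | None = None,
) -> ArtifactMask:
    """Classify every BBI; outlier labels take precedence over ectopic."""
    outlier_rule = outlier_rule if outlier_rule is not None else OutlierRule()
    ectopic_rule = ectopic_rule if ectopic_rule is not None else EctopicRule()
    outliers = detect_outliers(series, outlier_rule)
    n = series.bbis.size
    if n >= 2:
        ectopics = detect_ectopic(series, ectopic_rule, outlier_indices=outliers)
    else:
        ectopics = set()
    labels = np.full(n, CLEAN, dtype=object)
    for i in ectopics:
        labels[i] = ECTOPIC
    for i in outliers:
        labels[i] = OUTLIER
    return ArtifactMask(labels, outlier_rule=outlier_rule, ectopic_rule=ectopic_rule)
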