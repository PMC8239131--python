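"""1-min vs 5-min agreement: pairing, Pearson correlation, categories.

This module runs the whole pipeline over one or more recordings: artifact
mask → artifact-free 5-min window scan → greedy one-per-hour selection →
metrics on each selected window and on its first minute → per-metric Pearson
product-moment correlation R over the pooled pairs, classified as excellent
(R ≥ 0.9), good (0.7 ≤ R < 0.9), moderate (0.4 ≤ R < 0.7) or low (R < 0.4).
Pairing is structural — each 1-min value comes from the first minute of the
very 5-min window it is compared with — and pairs from all recordings are
pooled into a single correlation per metric.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import UndefinedMetricError, ValidationError
from .hrv_metrics import SpectralConfig, compute_metrics
from .preprocess import EctopicRule, OutlierRule, build_mask
from .rr_io import BeatSeries
from .segmenter import extract_first_minute, scan_clean_segments, select_hourly

__all__ = [
    "METRIC_NAMES",
    "StudyConfig",
    "ConcordanceResult",
    "pearson_r",
    "categorize_correlation",
    "run_concordance_study",
]

METRIC_NAMES = ("rmssd_ms", "sdnn_ms", "lf_ms2", "hf_ms2")


@dataclass(frozen=True)
class StudyConfig:
    """Every knob of the pipeline in one place; hashable for provenance."""

    outlier: OutlierRule = field(default_factory=OutlierRule)
    ectopic: EctopicRule = field(default_factory=EctopicRule)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    duration_s: float = 300.0
    short_duration_s: float = 60.0
    step_ms: float = 60_000.0
    spacing_min: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        out = raw.get("outlier", {})
        ect = raw.get("ectopic", {})
        spec = raw.get("spectral", {})
        seg = raw.get("segment", {})
        for key in ("lf_band", "hf_band"):
            if key in spec:
                spec[key] = tuple(spec[key])
        return cls(
            outlier=OutlierRule(**out),
            ectopic=EctopicRule(**ect),
            spectral=SpectralConfig(**spec),
            duration_s=seg.get("duration_s", 300.0),
            short_duration_s=seg.get("short_duration_s", 60.0),
            step_ms=seg.get("step_ms", 60_000.0),
            spacing_min=seg.get("spacing_min", 60.0),
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement of one metric's 1-min values with its 5-min values."""

    metric_name: str
    pearson_r: float
    category: str
    n_pairs: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input rather than
    silently returning 0."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    if xa.size < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = float(np.sqrt(np.sum(xd * xd)))
    sy = float(np.sqrt(np.sum(yd * yd)))
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("correlation undefined for a constant sequence")
    r = float(np.dot(xd, yd) / (sx * sy))
    return min(1.0, max(-1.0, r))


def categorize_correlation(r: float) -> str:
    """Half-open agreement bins: ≥0.9 excellent, ≥0.7 good, ≥0.4 moderate,
    else low (negative R is simply low; no absolute value)."""
    if not (-1.0 <= r <= 1.0) or np.isnan(r):
        raise ValidationError(f"correlation must lie in [-1, 1], got {r!r}")
    if r >= 0.9:
        return "excellent"
    if r >= 0.7:
        return "good"
    if r >= 0.4:
        return "moderate"
    return "low"


def run_concordance_study(
    recordings: BeatSeries | Iterable[BeatSeries],
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, list[ConcordanceResult], dict]:
    """Full pipeline over one or more recordings.

    Returns the long-format paired table (one row per selected segment and
    metric), per-metric :class:`ConcordanceResult` objects, and a run report
    with per-recording segment counts, exclusion notes, per-recording
    correlations where computable, and the config hash.  Deterministic given
    inputs and config.
    """
    config = config if config is not None else StudyConfig()
    if isinstance(recordings, BeatSeries):
        recordings = [recordings]
    recordings = list(recordings)
    if not recordings:
        raise ValidationError("at least one recording is required")

    rows: list[dict] = []
    per_recording: dict[str, dict] = {}
    for series in recordings:
        mask = build_mask(series, config.outlier, config.ectopic)
        candidates = scan_clean_segments(
            series, mask, duration_s=config.duration_s, step_ms=config.step_ms
        )
        selected = select_hourly(candidates, spacing_min=config.spacing_min)
        info = {
            "n_bbis": int(series.bbis.size),
            "n_artifact_bbis": int(mask.artifact_indices.size),
            "n_candidates": len(candidates),
            "n_selected": len(selected),
        }
        if not candidates:
            info["exclusion"] = (
                "recording shorter than the window"
                if series.duration_ms < config.duration_s * 1000.0
                else "no artifact-free window on the scan grid"
            )
        per_recording[series.recording_id] = info
        for seg in selected:
            m5 = compute_metrics(seg, config.spectral)
            m1 = compute_metrics(
                extract_first_minute(seg, config.short_duration_s), config.spectral
            )
            for name in METRIC_NAMES:
                rows.append(
                    {
                        "recording_id": series.recording_id,
                        "start_ms": float(seg.start_ms),
                        "metric": name,
                        "value_5min": getattr(m5, name),
                        "value_1min": getattr(m1, name),
                    }
                )

    pairs = pd.DataFrame(rows, columns=["recording_id", "start_ms", "metric", "value_5min", "value_1min"])
    results: list[ConcordanceResult] = []
    report: dict = {
        "config_hash": config.config_hash(),
        "n_recordings": len(recordings),
        "recordings": per_recording,
        "n_pairs": 0 if pairs.empty else int(pairs.groupby("metric").size().iloc[0]),
    }
    if pairs.empty:
        report["exclusion"] = "no segments selected in any recording"
        return pairs, results, report

    per_rec_r: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        sub = pairs[pairs["metric"] == name].dropna(subset=["value_5min", "value_1min"])
        try:
            r = pearson_r(sub["value_5min"].to_numpy(), sub["value_1min"].to_numpy())
            results.append(
                ConcordanceResult(name, r, categorize_correlation(r), int(len(sub)))
            )
        except (ValidationError, UndefinedMetricError) as exc:
            report.setdefault("undefined_metrics", {})[name] = str(exc)
        for rid, rec_sub in sub.groupby("recording_id"):
            try:
                per_rec_r.setdefault(rid, {})[name] = pearson_r(
                    rec_sub["value_5min"].to_numpy(), rec_sub["value_1min"].to_numpy()
                )
            except (ValidationError, UndefinedMetricError):
                pass
    report["per_recording_r"] = per_rec_r
    return pairs, results, report
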