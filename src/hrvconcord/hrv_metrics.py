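"""Time- and frequency-domain HRV metrics for one segment.

Time domain: RMSSD (root mean square of successive BBI differences) and SDNN
(sample standard deviation of the BBIs, n-1 divisor).  Frequency domain: LF
(0.04-0.15 Hz) and HF (0.15-0.40 Hz) band powers of the tachogram in ms².

The tachogram — BBI as a function of time — is unevenly sampled (one point
per beat, at the interval's end time).  The default estimator resamples it
with a cubic spline onto a uniform 4 Hz grid, removes the mean, and applies
Welch's method (Hann window, 256-sample segments, 50% overlap); band power is
the trapezoidal integral of the PSD over the band.  A Lomb-Scargle estimator
operating directly on the uneven points is available as a robustness check;
its periodogram is scaled like the classical periodogram PSD (a sinusoid of
amplitude A integrates to A²/2 over its peak), so the two estimators are
comparable in absolute ms² units.

The same code path serves 5-minute and 1-minute windows.  A 1-minute window
covers only 2.4 cycles of the 0.04 Hz LF band edge, so LF estimates there are
resolution-limited; a :class:`ResolutionWarning` is attached but the value is
still computed and reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, welch

from .exceptions import ResolutionWarning, UndefinedMetricError, ValidationError
from .segmenter import Segment

__all__ = [
    "HRVMetrics",
    "SpectralConfig",
    "rmssd",
    "sdnn",
    "tachogram",
    "band_power",
    "compute_metrics",
    "lf_period_coverage",
]

#: warn when a window covers fewer than this many cycles of the LF band edge
_MIN_LF_CYCLES = 5.0


@dataclass(frozen=True)
class SpectralConfig:
    """Band definitions and spectral-estimation parameters."""

    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    resample_hz: float = 4.0
    estimator: str = "welch"  # or "lomb_scargle"
    window: str = "hann"
    seg_len_samples: int = 256
    overlap_frac: float = 0.5
    detrend: str = "mean"

    def __post_init__(self) -> None:
        lo_l, hi_l = self.lf_band
        lo_h, hi_h = self.hf_band
        if not (0 < lo_l < hi_l and 0 < lo_h < hi_h):
            raise ValidationError("band bounds must be positive and ordered")
        if hi_l != lo_h:
            raise ValidationError("LF upper edge must equal HF lower edge")
        if self.estimator not in ("welch", "lomb_scargle"):
            raise ValidationError(f"unknown estimator: {self.estimator!r}")
        if self.resample_hz <= 2 * hi_h:
            raise ValidationError("resample_hz must exceed twice the HF upper edge")
        if not (0 <= self.overlap_frac < 1):
            raise ValidationError("overlap_frac must be in [0, 1)")


@dataclass(frozen=True)
class HRVMetrics:
    """Metric bundle for one window; frequency metrics are NaN when the
    window holds too few beats for spectral estimation."""

    rmssd_ms: float
    sdnn_ms: float
    lf_ms2: float
    hf_ms2: float
    duration_s: float
    n_bbis: int
    recording_id: str
    start_ms: float


def rmssd(bbis: np.ndarray) -> float:
    """Root mean square of successive differences, ms."""
    b = np.asarray(bbis, dtype=np.float64)
    if b.size < 2:
        raise UndefinedMetricError("RMSSD needs at least 2 BBIs")
    d = np.diff(b)
    return float(np.sqrt(np.mean(d * d)))


def sdnn(bbis: np.ndarray) -> float:
    """Sample standard deviation of the BBIs (n-1 divisor), ms."""
    b = np.asarray(bbis, dtype=np.float64)
    if b.size < 2:
        raise UndefinedMetricError("SDNN needs at least 2 BBIs")
    return float(np.std(b, ddof=1))


def tachogram(
    segment: Segment, resample_hz: float = 4.0, detrend: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resampled BBI series over the window.

    Each contained BBI is a sample at its end-beat time; a cubic spline
    interpolates onto a uniform grid of ``duration_s * resample_hz`` points
    spanning the window.  Returns ``(times_s, values_ms)`` with times
    relative to the window start; the mean is removed when ``detrend``.
    """
    bbis = segment.bbis
    if bbis.size < 4:
        raise UndefinedMetricError("tachogram needs at least 4 contained BBIs")
    t_pts = (segment.beat_times[1:] - segment.start_ms) / 1000.0  # BBI end times, s
    spline = CubicSpline(t_pts, bbis, extrapolate=True)
    n = round(segment.duration_s * resample_hz)
    grid = np.arange(n) / resample_hz
    values = spline(grid)
    if detrend:
        values = values - values.mean()
    return grid, values


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if np.count_nonzero(sel) < 2:
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def band_power(segment: Segment, config: SpectralConfig | None = None) -> tuple[float, float]:
    """(LF, HF) band power in ms² for one segment."""
    config = config if config is not None else SpectralConfig()
    if segment.duration_s * config.lf_band[0] < _MIN_LF_CYCLES:
        warnings.warn(
            f"window of {segment.duration_s:g} s covers only "
            f"{lf_period_coverage(segment.duration_s, config.lf_band[0]):.2g} cycles "
            f"of the {config.lf_band[0]:g} Hz LF edge; LF power is resolution-limited",
            ResolutionWarning,
            stacklevel=2,
        )
    if config.estimator == "welch":
        _, x = tachogram(segment, config.resample_hz, detrend=(config.detrend == "mean"))
        nperseg = min(config.seg_len_samples, x.size)
        freqs, psd = welch(
            x,
            fs=config.resample_hz,
            window=config.window,
            nperseg=nperseg,
            noverlap=int(config.overlap_frac * nperseg),
            detrend="constant",
        )
    else:
        freqs, psd = _lomb_scargle_psd(segment, config)
    return _integrate_band(freqs, psd, config.lf_band), _integrate_band(
        freqs, psd, config.hf_band
    )


def _lomb_scargle_psd(segment: Segment, config: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    """Variance-normalised Lomb-Scargle PSD of the uneven (time, BBI) points."""
    bbis = segment.bbis
    if bbis.size < 4:
        raise UndefinedMetricError("spectral estimate needs at least 4 contained BBIs")
    t = (segment.beat_times[1:] - segment.start_ms) / 1000.0
    y = bbis - bbis.mean()
    duration = segment.duration_s
    df = 1.0 / (2.0 * duration)  # 2x frequency oversampling
    freqs = np.arange(df, config.resample_hz / 2.0 + df / 2, df)
    if float(np.var(y)) < 1e-12:
        return freqs, np.zeros_like(freqs)
    pgram = lombscargle(t, y, 2.0 * math.pi * freqs)
    # classical periodogram PSD scaling generalised to uneven sampling:
    # a sinusoid of amplitude A then integrates to A^2/2 over its peak
    return freqs, pgram * (2.0 * duration / y.size)


def compute_metrics(segment: Segment, config: SpectralConfig | None = None) -> HRVMetrics:
    """Assemble RMSSD, SDNN, LF and HF for one window (any duration)."""
    config = config if config is not None else SpectralConfig()
    bbis = segment.bbis
    if bbis.size < 2:
        raise UndefinedMetricError("segment holds fewer than 2 contained BBIs")
    try:
        lf, hf = band_power(segment, config)
    except UndefinedMetricError:
        lf, hf = float("nan"), float("nan")
    return HRVMetrics(
        rmssd_ms=rmssd(bbis),
        sdnn_ms=sdnn(bbis),
        lf_ms2=lf,
        hf_ms2=hf,
        duration_s=segment.duration_s,
        n_bbis=int(bbis.size),
        recording_id=segment.parent.recording_id,
        start_ms=float(segment.start_ms),
    )


def lf_period_coverage(window_s: float, lf_low_hz: float = 0.04) -> float:
    """Number of cycles of the LF band's lowest frequency inside a window.

    A 60 s window covers only 2.4 cycles of 0.04 Hz — the structural reason
    ultra-short LF estimates are noisier than 5-minute ones.
    """
    if window_s <= 0 or lf_low_hz <= 0:
        raise ValidationError("window_s and lf_low_hz must be positive")
    return window_s * lf_low_hz
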