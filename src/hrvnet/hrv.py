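"""Heart-rate-variability metrics from R-R interval series.

Time-domain metrics are the coefficient of variation (VC = sd/mean of the
R-R intervals) and RMSSD (root mean square of successive interval
differences).  Frequency-domain metrics are the low-frequency
(0.04-0.14 Hz) and high-frequency (0.15-0.50 Hz) band powers of the
tachogram power spectral density, obtained by cubic interpolation of the
irregularly sampled intervals onto a uniform 4 Hz grid followed by an
FFT periodogram (Hann window, linear detrend).

Subject metrics are referenced to a healthy-control cohort by z-scoring;
only *reductions* are classified as abnormal (z < -1, strictly), because
there is no meaningful upper limit for HRV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.signal import periodogram

__all__ = [
    "RRISeries",
    "Spectrum",
    "HRVMetrics",
    "ControlNorms",
    "ZScorePanel",
    "clean_rr",
    "time_domain",
    "rr_psd",
    "band_power",
    "compute_metrics",
    "zscore_panel",
    "LF_BAND",
    "HF_BAND",
    "METRIC_NAMES",
]

#: Spectral band edges in Hz (half-open intervals [lo, hi)).
LF_BAND = (0.04, 0.14)
HF_BAND = (0.15, 0.50)

METRIC_NAMES = ("vc", "rmssd", "lf_power", "hf_power")


@dataclass
class RRISeries:
    """A sequence of R-R intervals with their beat times.

    ``beat_times`` are in seconds (strictly increasing, one per beat);
    ``intervals`` are in milliseconds (one per beat pair, so
    ``len(intervals) == len(beat_times) - 1``).
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    cleaned_flags: np.ndarray = None  # type: ignore[assignment]
    quality_ok: bool = True
    n_replaced: int = 0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.cleaned_flags is None:
            self.cleaned_flags = np.zeros(self.intervals.size, dtype=bool)
        self.cleaned_flags = np.asarray(self.cleaned_flags, dtype=bool)
        if self.intervals.size != self.beat_times.size - 1:
            raise ValueError("intervals must have one fewer element than beat_times")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be strictly positive")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        implied = np.diff(self.beat_times) * 1000.0
        if not np.allclose(implied, self.intervals, rtol=1e-6, atol=1e-6):
            raise ValueError("intervals inconsistent with beat_times")

    @classmethod
    def from_intervals(cls, intervals_ms: np.ndarray, t0: float = 0.0) -> "RRISeries":
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = t0 + np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
        return cls(beat_times=beat_times, intervals=intervals_ms)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    def write_csv(self, path) -> None:
        df = pd.DataFrame(
            {"beat_time_s": self.beat_times[:-1], "rr_ms": self.intervals}
        )
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "RRISeries":
        df = pd.read_csv(path)
        return cls.from_intervals(
            df["rr_ms"].to_numpy(), t0=float(df["beat_time_s"].iloc[0])
        )


@dataclass
class Spectrum:
    """One-sided power spectral density of the tachogram (ms^2/Hz)."""

    freqs: np.ndarray
    density: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class HRVMetrics:
    vc: float
    rmssd: float
    lf_power: float
    hf_power: float
    mean_rr: float
    n_beats: int

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class ControlNorms:
    """Per-metric mean/sd from a healthy control cohort."""

    means: dict
    sds: dict
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need at least 2 control subjects")
        for name, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"control sd for {name!r} must be > 0")

    @classmethod
    def from_cohort(cls, cohort: list) -> "ControlNorms":
        if len(cohort) < 2:
            raise ValueError("need at least 2 control subjects")
        values = {m: np.array([getattr(s, m) for s in cohort]) for m in METRIC_NAMES}
        means = {m: float(v.mean()) for m, v in values.items()}
        sds = {m: float(v.std(ddof=1)) for m, v in values.items()}
        return cls(means=means, sds=sds, n_controls=len(cohort))


@dataclass
class ZScorePanel:
    z: dict
    abnormal: dict

    def any_abnormal(self) -> bool:
        return any(self.abnormal.values())


def clean_rr(raw: RRISeries, rel_tol: float = 0.30) -> RRISeries:
    """Flag ectopic intervals and replace them by local interpolation.

    An interval deviating by more than ``rel_tol`` (fractional) from the
    running 5-point median is treated as ectopic and replaced by linear
    interpolation between its nearest accepted neighbours.  If more than
    20 % of intervals are flagged, a warning is emitted and the series'
    ``quality_ok`` flag is cleared (the series is still returned).
    """
    x = raw.intervals
    if x.size < 3:
        raise ValueError("need at least 3 intervals to clean")
    ref = median_filter(x, size=5, mode="nearest")
    flagged = np.abs(x - ref) > rel_tol * ref
    cleaned = x.copy()
    quality_ok = True
    if flagged.any():
        good = ~flagged
        if good.sum() >= 2:
            idx = np.arange(x.size)
            cleaned[flagged] = np.interp(idx[flagged], idx[good], x[good])
        else:  # nearly everything flagged: fall back to the median level
            cleaned[flagged] = np.median(ref)
        if flagged.mean() > 0.20:
            warnings.warn(
                f"{flagged.mean():.0%} of intervals flagged as ectopic; "
                "series quality questionable",
                stacklevel=2,
            )
            quality_ok = False
    beat_times = raw.beat_times[0] + np.concatenate(
        [[0.0], np.cumsum(cleaned) / 1000.0]
    )
    return RRISeries(
        beat_times=beat_times,
        intervals=cleaned,
        cleaned_flags=flagged,
        quality_ok=quality_ok,
        n_replaced=int(flagged.sum()),
    )


def time_domain(rr: RRISeries) -> tuple:
    """Return ``(vc, rmssd)``.

    VC uses the sample (n-1) standard deviation, matching the cohort
    z-scoring convention; RMSSD is in ms.
    """
    x = rr.intervals
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    vc = float(x.std(ddof=1) / x.mean())
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return vc, rmssd


def rr_psd(rr: RRISeries, resample_hz: float = 4.0) -> Spectrum:
    """Power spectral density of the tachogram (ms^2/Hz).

    The interval series is interpolated (cubic spline) onto a uniform
    ``resample_hz`` grid over the recording, linearly detrended and
    windowed (Hann, power-corrected) before the FFT periodogram.
    """
    if rr.duration < 60.0:
        raise ValueError("recording shorter than 60 s; spectral metrics unreliable")
    t = rr.beat_times[:-1]  # interval value attributed to its starting beat
    spline = CubicSpline(t, rr.intervals)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    x = spline(grid)
    freqs, density = periodogram(
        x, fs=resample_hz, window="hann", detrend="linear", scaling="density"
    )
    return Spectrum(freqs=freqs, density=density)


def band_power(spectrum: Spectrum, band: tuple) -> float:
    """Integrated spectral power (ms^2) over the half-open band [lo, hi).

    Integration is rectangular (bin width times density) over the
    frequency bins whose centre lies in the band, which makes power
    exactly additive over disjoint bands.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy f_lo < f_hi")
    freqs = spectrum.freqs
    df = spectrum.df
    if lo < freqs[0] - df / 2 or hi > freqs[-1] + df:
        raise ValueError("band outside the spectrum frequency range")
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(spectrum.density[mask].sum() * df)


def compute_metrics(
    rr: RRISeries,
    lf_band: tuple = LF_BAND,
    hf_band: tuple = HF_BAND,
    resample_hz: float = 4.0,
) -> HRVMetrics:
    """All four HRV metrics for one subject."""
    vc, rmssd = time_domain(rr)
    spec = rr_psd(rr, resample_hz=resample_hz)
    return HRVMetrics(
        vc=vc,
        rmssd=rmssd,
        lf_power=band_power(spec, lf_band),
        hf_power=band_power(spec, hf_band),
        mean_rr=float(rr.intervals.mean()),
        n_beats=rr.n_beats,
    )


def zscore_panel(
    metrics: HRVMetrics, norms: ControlNorms, z_thresh: float = -1.0
) -> ZScorePanel:
    """Z-score each metric against control norms; abnormal iff z < z_thresh.

    The inequality is strict: a subject sitting exactly one control
    standard deviation below the mean (z = -1) is *not* abnormal.
    """
    z = {}
    abnormal = {}
    for name in METRIC_NAMES:
        sd = norms.sds[name]
        if sd <= 0:
            raise ValueError(f"control sd for {name!r} must be > 0")
        z[name] = (getattr(metrics, name) - norms.means[name]) / sd
        abnormal[name] = bool(z[name] < z_thresh)
    return ZScorePanel(z=z, abnormal=abnormal)
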