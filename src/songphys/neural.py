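"""Multi-unit neural analysis.

Noise estimation with the MAD/0.6745 estimator, negative-threshold spike
detection on band-passed traces, signal-to-noise ratio, onset-aligned
rasters, Gaussian-kernel rate traces, windowed count statistics (mean rate,
variance, Fano factor), pairwise normalization and correlation of rate
traces, and the rendition-count / minimum-rate inclusion filter.

All windows are half-open ``[start, end)`` in seconds relative to the
alignment event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy import signal, stats

from songphys.audio import Waveform
from songphys.errors import DataError, ParameterError

__all__ = [
    "SpikeTrain",
    "AlignedRaster",
    "RateTrace",
    "WindowedStats",
    "bandpass_trace",
    "estimate_noise_level",
    "detect_spikes",
    "compute_snr",
    "align_raster",
    "smooth_rate",
    "windowed_counts",
    "percent_rate_change",
    "normalize_pair",
    "rate_correlation",
    "apply_neural_inclusion",
]

DEFAULT_BAND = (300.0, 4000.0)
MAD_SCALE = 0.6745  # MAD of a standard normal


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s) from one trace."""

    times: np.ndarray
    source: str = ""
    peaks: np.ndarray | None = None  # filtered-trace amplitude at each event

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if self.peaks is not None:
            object.__setattr__(
                self, "peaks", np.asarray(self.peaks, dtype=np.float64)
            )
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ParameterError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class AlignedRaster:
    """Onset-aligned spike times, one array of relative times per rendition."""

    window: tuple[float, float]
    trains: list[np.ndarray]
    label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        t0, t1 = self.window
        if not t0 < t1:
            raise ParameterError("window start must precede end")
        trains = [np.asarray(t, dtype=np.float64) for t in self.trains]
        object.__setattr__(self, "trains", trains)
        for t in trains:
            if t.size and (t.min() < t0 or t.max() >= t1):
                raise ParameterError("relative spike times must lie in the window")

    @property
    def n_renditions(self) -> int:
        return len(self.trains)


@dataclass(frozen=True)
class RateTrace:
    """Mean +/- s.e.m. kernel-smoothed firing rate on a uniform grid."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    kernel_sd: float

    def __post_init__(self) -> None:
        for name in ("times", "mean", "sem"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64)
            )


class WindowedStats(NamedTuple):
    counts: np.ndarray
    mean_rate: float  # Hz
    variance: float  # across-rendition sample variance of counts
    fano: float  # variance / mean count; NaN when mean count is 0


def bandpass_trace(
    trace: Waveform, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of a voltage trace."""
    lo, hi = band
    nyq = trace.rate / 2
    if not 0 < lo < hi < nyq:
        raise ParameterError(f"band {band} must lie within (0, {nyq}) Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=trace.rate, output="sos")
    if trace.samples.size < 100:
        raise DataError("trace shorter than the filter transient")
    return signal.sosfiltfilt(sos, trace.samples)


def estimate_noise_level(
    trace: Waveform, band: tuple[float, float] = DEFAULT_BAND
) -> float:
    """Robust noise SD of the band-passed trace: median(|x - median|)/0.6745.

    The median-absolute-deviation estimator avoids the upward bias a plain
    standard deviation would pick up from spike events.
    """
    filtered = bandpass_trace(trace, band)
    return float(np.median(np.abs(filtered - np.median(filtered))) / MAD_SCALE)


def detect_spikes(
    trace: Waveform,
    low_mult: float = 3.5,
    high_mult: float = 50.0,
    refractory: float = 0.0002,
    band: tuple[float, float] = DEFAULT_BAND,
) -> SpikeTrain:
    """Negative-threshold multi-unit event detection.

    The trace is band-passed; candidate events are local negative peaks
    below ``-low_mult * noise``; events with ``|peak| >= high_mult * noise``
    are discarded as artifacts; of two events closer than ``refractory``
    the earlier is kept.
    """
    filtered = bandpass_trace(trace, band)
    noise = float(np.median(np.abs(filtered - np.median(filtered))) / MAD_SCALE)
    if noise <= 0:
        raise DataError("zero noise estimate; cannot set detection threshold")
    idx, _ = signal.find_peaks(-filtered, height=low_mult * noise)
    peaks = filtered[idx]
    keep_amp = np.abs(peaks) < high_mult * noise
    idx, peaks = idx[keep_amp], peaks[keep_amp]
    times = idx / trace.rate
    keep: list[int] = []
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= refractory:
            keep.append(i)
            last = t
    return SpikeTrain(times=times[keep], peaks=peaks[keep])


def compute_snr(trace: Waveform, st: SpikeTrain,
                band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Mean absolute negative-peak amplitude over the noise estimate."""
    if len(st) == 0:
        raise DataError("no detected events")
    if st.peaks is None:
        raise DataError("spike train carries no peak amplitudes")
    noise = estimate_noise_level(trace, band)
    return float(np.mean(np.abs(st.peaks)) / noise)


def align_raster(
    st: SpikeTrain, onsets, window: tuple[float, float],
    label: str = "", condition: str = "",
) -> AlignedRaster:
    """One rendition per onset; relative spike times kept if in ``[t0, t1)``."""
    t0, t1 = window
    if not t0 < t1:
        raise ParameterError("window start must precede end")
    onsets = np.asarray(onsets, dtype=np.float64)
    trains = []
    for onset in onsets:
        rel = st.times - onset
        trains.append(rel[(rel >= t0) & (rel < t1)])
    return AlignedRaster(window=window, trains=trains, label=label,
                         condition=condition)


def smooth_rate(
    r: AlignedRaster, kernel_sd: float = 0.005, grid_step: float = 0.001
) -> RateTrace:
    """Rendition-averaged firing rate from unit-integral Gaussian kernels.

    Each rendition's rate is the sum of Gaussian kernels (SD ``kernel_sd``,
    units Hz) centered at its spike times, evaluated on a uniform grid;
    mean and s.e.m. are taken across renditions. No edge renormalization is
    applied.
    """
    if r.n_renditions < 1:
        raise DataError("raster has no renditions")
    t0, t1 = r.window
    grid = np.arange(t0, t1 + grid_step / 2, grid_step)
    norm = 1.0 / (np.sqrt(2 * np.pi) * kernel_sd)
    per_rendition = np.zeros((r.n_renditions, grid.size))
    for i, train in enumerate(r.trains):
        if train.size:
            z = (grid[None, :] - train[:, None]) / kernel_sd
            per_rendition[i] = norm * np.exp(-0.5 * z**2).sum(axis=0)
    mean = per_rendition.mean(axis=0)
    if r.n_renditions > 1:
        sem = per_rendition.std(axis=0, ddof=1) / np.sqrt(r.n_renditions)
    else:
        sem = np.zeros_like(mean)
    return RateTrace(times=grid, mean=mean, sem=sem, kernel_sd=kernel_sd)


def windowed_counts(r: AlignedRaster, window: tuple[float, float]) -> WindowedStats:
    """Per-rendition spike counts in a half-open window, with mean rate,
    sample variance, and Fano factor (variance / mean count)."""
    w0, w1 = window
    if not (r.window[0] <= w0 < w1 <= r.window[1]):
        raise ParameterError("statistics window must lie within the raster window")
    counts = np.array(
        [np.count_nonzero((t >= w0) & (t < w1)) for t in r.trains], dtype=float
    )
    mean_count = counts.mean()
    variance = float(counts.var(ddof=1)) if counts.size > 1 else float("nan")
    fano = float(variance / mean_count) if mean_count > 0 else float("nan")
    return WindowedStats(
        counts=counts,
        mean_rate=float(mean_count / (w1 - w0)),
        variance=variance,
        fano=fano,
    )


def percent_rate_change(
    r_base: AlignedRaster, r_treat: AlignedRaster, window: tuple[float, float]
) -> float:
    """100 * (treatment mean rate - baseline mean rate) / baseline mean rate."""
    base = windowed_counts(r_base, window).mean_rate
    treat = windowed_counts(r_treat, window).mean_rate
    if base == 0:
        raise DataError("zero baseline mean rate")
    return 100.0 * (treat - base) / base


def normalize_pair(
    a: RateTrace, b: RateTrace, window: tuple[float, float] = (-0.05, 0.05)
) -> tuple[RateTrace, RateTrace]:
    """Divide both mean traces by the joint maximum within the window."""
    w0, w1 = window
    mask_a = (a.times >= w0) & (a.times < w1)
    mask_b = (b.times >= w0) & (b.times < w1)
    if not mask_a.any() or not mask_b.any():
        raise ParameterError("normalization window contains no grid points")
    joint_max = max(float(a.mean[mask_a].max()), float(b.mean[mask_b].max()))
    if joint_max <= 0:
        raise DataError("joint maximum in the window is zero")
    return (
        RateTrace(a.times, a.mean / joint_max, a.sem / joint_max, a.kernel_sd),
        RateTrace(b.times, b.mean / joint_max, b.sem / joint_max, b.kernel_sd),
    )


def rate_correlation(a: RateTrace, b: RateTrace) -> float:
    """Pearson correlation of two mean-rate traces on identical grids."""
    if a.times.size != b.times.size or not np.allclose(a.times, b.times):
        raise ParameterError("rate traces must share an identical time grid")
    if np.allclose(a.mean, a.mean[0]) or np.allclose(b.mean, b.mean[0]):
        raise DataError("zero variance in a rate trace")
    r, _ = stats.pearsonr(a.mean, b.mean)
    return float(r)


def apply_neural_inclusion(
    pairs: Iterable[tuple[AlignedRaster, AlignedRaster]],
    min_renditions: int = 10,
    min_rate: float = 50.0,
    rate_window: tuple[float, float] = (-0.05, 0.05),
) -> tuple[list[tuple[AlignedRaster, AlignedRaster]], list[str]]:
    """Filter site x syllable raster pairs.

    A pair is excluded if either condition has fewer than
    ``min_renditions`` renditions or a mean rate below ``min_rate`` Hz in
    the onset-centered window. Returns the retained pairs and a reason per
    exclusion.
    """
    kept: list[tuple[AlignedRaster, AlignedRaster]] = []
    reasons: list[str] = []
    for i, (base, treat) in enumerate(pairs):
        name = base.label or f"pair{i}"
        if min(base.n_renditions, treat.n_renditions) < min_renditions:
            reasons.append(f"{name}: fewer than {min_renditions} renditions")
            continue
        rates = (
            windowed_counts(base, rate_window).mean_rate,
            windowed_counts(treat, rate_window).mean_rate,
        )
        if min(rates) < min_rate:
            reasons.append(f"{name}: mean rate below {min_rate} Hz")
            continue
        kept.append((base, treat))
    return kept, reasons
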