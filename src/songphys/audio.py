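"""Acoustic feature extraction from song waveforms.

Implements the measurement chain used throughout the package: band-passed
RMS amplitude envelopes, threshold segmentation into syllables,
Gaussian-windowed spectrograms, pitch contours refined by parabolic
interpolation of log power, per-syllable pitch/amplitude/duration
measurements, the iterated 4xMAD outlier rule, and the coefficient of
variation.

Conventions: all times are seconds, sample indices are 0-based, and every
interval is half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.ndimage import uniform_filter1d

from songphys.errors import DataError, ParameterError

__all__ = [
    "Waveform",
    "Envelope",
    "SyllableEvent",
    "PitchContour",
    "SpectrogramParams",
    "Spectrogram",
    "compute_envelope",
    "segment_syllables",
    "compute_spectrogram",
    "extract_pitch_contour",
    "measure_syllable_pitch",
    "measure_syllable_amplitude",
    "measure_durations",
    "remove_outliers",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class Waveform:
    """A sampled signal (audio or voltage) in arbitrary linear units."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ParameterError(f"sample rate must be positive, got {self.rate}")
        if samples.ndim != 1:
            raise ParameterError("waveform must be one-dimensional (mono)")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ParameterError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def segment(self, onset: float, offset: float) -> "Waveform":
        """Samples covering the half-open interval ``[onset, offset)``."""
        i0 = max(0, int(round(onset * self.rate)))
        i1 = min(self.samples.size, int(round(offset * self.rate)))
        return Waveform(self.samples[i0:i1], self.rate)


@dataclass(frozen=True)
class Envelope:
    """A nonnegative RMS amplitude envelope, sampled at the source rate."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if self.rate <= 0:
            raise ParameterError("envelope rate must be positive")
        if values.size and values.min() < 0:
            raise ParameterError("envelope values must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass(frozen=True)
class SyllableEvent:
    """One labeled syllable occurrence: half-open interval ``[onset, offset)``."""

    onset: float
    offset: float
    label: str = ""
    bout_id: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ParameterError(
                f"offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SpectrogramParams:
    """Short-time Fourier transform parameters.

    ``window_sd`` is the Gaussian window standard deviation in seconds
    (allowed 1-3 ms), truncated to ``window_size`` samples.
    """

    window_sd: float = 0.002
    window_size: int = 1024
    hop: int = 4
    fft_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.001 <= self.window_sd <= 0.003:
            raise ParameterError("window_sd must lie in [0.001, 0.003] s")
        if not 0 < self.hop <= self.window_size:
            raise ParameterError("require 0 < hop <= window_size")
        if self.fft_size is not None and self.fft_size < self.window_size:
            raise ParameterError("fft_size must be >= window_size")

    @property
    def nfft(self) -> int:
        return self.window_size if self.fft_size is None else self.fft_size


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency power matrix; ``power[i, j]`` at ``freqs[i]``, ``times[j]``."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class PitchContour:
    """Per-frame pitch estimates. ``edge`` flags frames whose spectral peak sat
    on a search-band boundary (un-interpolated bin frequency used)."""

    times: np.ndarray
    pitch: np.ndarray
    edge: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        pitch = np.asarray(self.pitch, dtype=np.float64)
        edge = (
            np.zeros(times.size, dtype=bool)
            if self.edge is None
            else np.asarray(self.edge, dtype=bool)
        )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pitch", pitch)
        object.__setattr__(self, "edge", edge)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ParameterError("contour times must be strictly increasing")


def bandpass_fir(w: Waveform, band: tuple[float, float], order: int = 80) -> np.ndarray:
    """Linear-phase FIR band-pass with group delay compensated.

    Uses a centered same-length convolution so that the output aligns
    sample-for-sample with the input.
    """
    lo, hi = band
    nyq = w.rate / 2
    if not 0 < lo < hi < nyq:
        raise ParameterError(f"band {band} must lie within (0, {nyq}) Hz")
    taps = signal.firwin(order + 1, [lo, hi], pass_zero=False, fs=w.rate)
    return np.convolve(w.samples, taps, mode="same")


def compute_envelope(
    w: Waveform,
    band: tuple[float, float] = (500.0, 10000.0),
    fir_order: int = 80,
    smooth: float = 0.0025,
) -> Envelope:
    """Band-passed RMS amplitude envelope.

    The waveform is band-pass filtered with a linear-phase FIR filter of the
    given order (group delay compensated), squared, averaged over a centered
    sliding rectangular window of length ``smooth`` seconds, and square-rooted.
    """
    filtered = bandpass_fir(w, band, fir_order)
    n_smooth = max(1, int(round(smooth * w.rate)))
    mean_sq = uniform_filter1d(filtered**2, size=n_smooth, mode="nearest")
    return Envelope(np.sqrt(np.clip(mean_sq, 0.0, None)), w.rate)


def segment_syllables(
    e: Envelope,
    threshold: float,
    min_syllable: float = 0.005,
    min_gap: float = 0.005,
) -> list[SyllableEvent]:
    """Threshold the envelope into syllable events.

    Onsets are upward threshold crossings and offsets downward crossings;
    gaps shorter than ``min_gap`` are merged and events shorter than
    ``min_syllable`` dropped. Returned events carry no labels.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    above = e.values > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        stops = np.append(stops, above.size)

    merged: list[list[int]] = []
    min_gap_n = min_gap * e.rate
    for s, t in zip(starts, stops):
        if merged and s - merged[-1][1] < min_gap_n:
            merged[-1][1] = t
        else:
            merged.append([s, t])

    min_syl_n = min_syllable * e.rate
    return [
        SyllableEvent(onset=s / e.rate, offset=t / e.rate)
        for s, t in merged
        if t - s >= min_syl_n
    ]


def compute_spectrogram(w: Waveform, p: SpectrogramParams | None = None) -> Spectrogram:
    """Gaussian-windowed short-time power spectrogram.

    Frames start at multiples of ``p.hop``; only complete frames are kept.
    Column times are window centers; power is the squared magnitude of the
    one-sided FFT; the frequency step is ``rate / fft_size``.
    """
    p = p or SpectrogramParams()
    x = w.samples
    if x.size < p.window_size:
        raise DataError(
            f"input of {x.size} samples is shorter than the {p.window_size}-sample window"
        )
    win = signal.windows.gaussian(p.window_size, std=p.window_sd * w.rate)
    frames = sliding_window_view(x, p.window_size)[:: p.hop]
    spec = np.fft.rfft(frames * win, n=p.nfft, axis=1)
    power = np.abs(spec.T) ** 2
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * p.hop + (p.window_size - 1) / 2) / w.rate
    freqs = np.fft.rfftfreq(p.nfft, d=1.0 / w.rate)
    return Spectrogram(power=power, freqs=freqs, times=times)


def extract_pitch_contour(
    spec: Spectrogram, band: tuple[float, float]
) -> PitchContour:
    """Pitch contour from per-frame spectral peaks within a search band.

    In each column the maximum-power bin ``k`` inside ``band`` is refined by
    parabolic interpolation on log power::

        delta = 0.5 * (a - c) / (a - 2 b + c)

    with ``a, b, c`` the log powers at ``k-1, k, k+1``; ``delta`` is clamped
    to [-0.5, 0.5]. Peaks on a band edge are left at the bin frequency and
    flagged.
    """
    lo, hi = band
    in_band = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
    if in_band.size < 3:
        raise ParameterError(
            f"search band {band} must contain at least 3 frequency bins"
        )
    k_lo, k_hi = int(in_band[0]), int(in_band[-1])
    sub = spec.power[k_lo : k_hi + 1]
    peaks = k_lo + np.argmax(sub, axis=0)

    df = spec.df
    n_cols = spec.power.shape[1]
    pitch = np.empty(n_cols)
    edge = np.zeros(n_cols, dtype=bool)
    tiny = np.finfo(float).tiny
    logp = np.log(np.maximum(spec.power, tiny))
    for j in range(n_cols):
        k = peaks[j]
        if k in (k_lo, k_hi) or k == 0 or k == spec.power.shape[0] - 1:
            pitch[j] = k * df
            edge[j] = True
            continue
        a, b, c = logp[k - 1, j], logp[k, j], logp[k + 1, j]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        pitch[j] = (k + delta) * df
    return PitchContour(times=spec.times, pitch=pitch, edge=edge)


def measure_syllable_pitch(c: PitchContour, window: tuple[float, float]) -> float:
    """Mean contour pitch over the half-open time window; NaN if no overlap."""
    w0, w1 = window
    mask = (c.times >= w0) & (c.times < w1)
    if not mask.any():
        return float("nan")
    return float(np.mean(c.pitch[mask]))


def measure_syllable_amplitude(e: Envelope, ev: SyllableEvent) -> float:
    """Mean envelope over the middle 80% of the syllable."""
    dur = ev.duration
    i0 = int(round((ev.onset + 0.1 * dur) * e.rate))
    i1 = int(round((ev.offset - 0.1 * dur) * e.rate))
    i0 = max(0, i0)
    i1 = min(e.values.size, i1)
    if i1 - i0 < 3:
        raise DataError("syllable spans fewer than 3 envelope samples")
    return float(np.mean(e.values[i0:i1]))


def measure_durations(
    bout: list[SyllableEvent], sequence_spec: list[str]
) -> tuple[list[float], list[float], list[float]]:
    """Sequence, syllable, and gap durations for each occurrence of a motif.

    A match is a run of consecutive events whose labels equal
    ``sequence_spec``. Sequence duration is onset-of-last minus
    onset-of-first. Gaps are measured only inside matched sequences.
    Returns empty lists if the motif never occurs.
    """
    k = len(sequence_spec)
    if k < 1:
        raise ParameterError("sequence_spec must contain at least one label")
    labels = [ev.label for ev in bout]
    seq_durs: list[float] = []
    syl_durs: list[float] = []
    gap_durs: list[float] = []
    for i in range(len(bout) - k + 1):
        if labels[i : i + k] != sequence_spec:
            continue
        run = bout[i : i + k]
        seq_durs.append(run[-1].onset - run[0].onset)
        syl_durs.extend(ev.duration for ev in run)
        gap_durs.extend(
            nxt.onset - cur.offset for cur, nxt in zip(run[:-1], run[1:])
        )
    return seq_durs, syl_durs, gap_durs


def remove_outliers(values, n_passes: int = 3, n_mad: float = 4.0) -> np.ndarray:
    """Iterated median-absolute-deviation outlier removal.

    Runs exactly ``n_passes`` passes; each pass drops values farther than
    ``n_mad`` times the MAD from the median (both recomputed per pass). A
    pass with MAD = 0 drops nothing. The output is a subsequence of the
    input.
    """
    kept = np.asarray(values, dtype=np.float64)
    if kept.size == 0:
        raise DataError("cannot filter an empty sequence")
    for _ in range(n_passes):
        med = np.median(kept)
        mad = np.median(np.abs(kept - med))
        if mad == 0:
            continue
        kept = kept[np.abs(kept - med) <= n_mad * mad]
    return kept


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise DataError("coefficient of variation requires at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise DataError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)
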