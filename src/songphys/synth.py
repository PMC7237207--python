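"""Seeded generators for synthetic song audio and multi-unit spike data.

Song bouts are assembled from syllable templates (harmonic stacks, sweeps,
complex stack+sweep syllables, and band-limited noisy syllables) sequenced
by a first-order Markov chain with branch points and geometrically
distributed repeat runs. Rendition-to-rendition jitter of pitch, duration,
and amplitude is log-normal multiplicative (parameterized by coefficient of
variation); inter-syllable gaps are gamma distributed. Every generator is
deterministic given its seed and returns ground-truth tables alongside the
rendered data, so the extraction pipeline can be validated end to end.

Condition effects (fractional shifts of pitch, jitter, durations,
amplitude, transition probabilities, repeat continuation, and neural rate
gain) are injected through :class:`ConditionDeltas`; the carbachol-scale
defaults are available via :meth:`ConditionDeltas.carbachol`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from songphys.audio import Waveform
from songphys.errors import ParameterError
from songphys.neural import AlignedRaster

__all__ = [
    "SyllableTemplate",
    "SongModel",
    "ConditionDeltas",
    "RateProfile",
    "NeuralModel",
    "make_default_song_model",
    "make_default_neural_model",
    "apply_condition",
    "synthesize_bouts",
    "generate_spike_renditions",
    "render_voltage_trace",
]

END = "END"

_KINDS = ("stack", "sweep", "complex", "noisy")


@dataclass(frozen=True)
class SyllableTemplate:
    """Parameters of one syllable type.

    ``f0`` is the fundamental frequency; for ``noisy`` syllables the
    spectral content is 2-8 kHz band-limited noise and ``f0`` is ignored.
    The ``*_cv`` fields set multiplicative rendition-to-rendition jitter.
    """

    label: str
    kind: str
    f0: float
    duration: float
    n_harmonics: int = 5
    harmonic_rolloff: float = 0.6
    ramp: float = 0.003
    base_amplitude: float = 1.0
    pitch_cv: float = 0.0
    duration_cv: float = 0.0
    amplitude_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.f0 <= 0:
            raise ParameterError("f0 must be positive")
        if not self.duration > 2 * self.ramp:
            raise ParameterError("duration must exceed twice the ramp time")
        for name in ("pitch_cv", "duration_cv", "amplitude_cv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.n_harmonics < 1:
            raise ParameterError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class SongModel:
    """A generative song model.

    ``transitions`` maps each element label to a row of successor
    probabilities over element labels (or ``"END"``); repeat runs are
    collapsed, so no element transitions to itself. ``repeat_params`` gives
    the per-run continuation probability of repeat-type syllables.
    """

    templates: dict[str, SyllableTemplate]
    transitions: dict[str, dict[str, float]]
    start_label: str
    repeat_params: dict[str, float] = field(default_factory=dict)
    gap_mean: float = 0.040
    gap_cv: float = 0.25
    sample_rate: float = 32000.0
    noise_floor: float = 1e-3
    pad: float = 0.05

    def __post_init__(self) -> None:
        if self.gap_mean <= 0:
            raise ParameterError("gap_mean must be positive")
        for label, row in self.transitions.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"transition row for {label!r} sums to {total}, not 1"
                )
            if any(p < 0 or p > 1 for p in row.values()):
                raise ParameterError(f"probabilities for {label!r} outside [0, 1]")
            if row.get(label, 0.0) > 0:
                raise ParameterError(
                    f"self-transition for {label!r}: repeats belong in repeat_params"
                )
        for label, p in self.repeat_params.items():
            if not 0 <= p < 1:
                raise ParameterError(
                    f"continuation probability for {label!r} must lie in [0, 1)"
                )
        if self.start_label not in self.templates:
            raise ParameterError(f"unknown start label {self.start_label!r}")


@dataclass(frozen=True)
class ConditionDeltas:
    """Fractional condition effects applied on top of a baseline model.

    All shifts are fractional (0.012 means +1.2%); ``pitch_cv_scale`` is a
    multiplicative factor on the pitch jitter c.v.; ``transition_shift``
    maps a branch label to per-outcome probability offsets (summing to 0,
    keyed like the transition row); ``rate_gain`` multiplies neural rates
    by ``1 + rate_gain``.
    """

    pitch_shift: float = 0.0
    pitch_cv_scale: float = 1.0
    syllable_duration_shift: float = 0.0
    gap_duration_shift: float = 0.0
    amplitude_shift: float = 0.0
    transition_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    repeat_continuation_shift: float = 0.0
    rate_gain: float = 0.0

    @classmethod
    def carbachol(cls) -> "ConditionDeltas":
        """Carbachol-scale defaults: +1.2% pitch, -13% pitch c.v., -0.93%
        syllable and -3.2% gap durations, +8.3% amplitude, +9.9% rate."""
        return cls(
            pitch_shift=0.012,
            pitch_cv_scale=0.87,
            syllable_duration_shift=-0.0093,
            gap_duration_shift=-0.032,
            amplitude_shift=0.083,
            rate_gain=0.099,
        )


@dataclass(frozen=True)
class RateProfile:
    """Nonnegative firing-rate function: baseline plus Gaussian bumps.

    ``bumps`` is a tuple of ``(center_s, sd_s, amplitude_hz)`` triples
    evaluated relative to syllable onset.
    """

    baseline: float = 0.0
    bumps: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ParameterError("baseline rate must be nonnegative")
        for _, sd, amp in self.bumps:
            if sd <= 0 or amp < 0:
                raise ParameterError("bump sd must be > 0 and amplitude >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        rate = np.full(t.shape, float(self.baseline))
        for center, sd, amp in self.bumps:
            rate += amp * np.exp(-0.5 * ((t - center) / sd) ** 2)
        return rate

    def max_rate(self, window: tuple[float, float], n_grid: int = 2001) -> float:
        grid = np.linspace(window[0], window[1], n_grid)
        return float(self(grid).max())


@dataclass(frozen=True)
class NeuralModel:
    """Generative model of one multi-unit recording site."""

    rate_template: RateProfile
    baseline_rate: float = 150.0
    noise_sigma: float = 1.0
    spike_peak_sigma: float = 6.0
    refractory: float = 0.0002
    sample_rate: float = 30000.0

    def __post_init__(self) -> None:
        if self.refractory <= 0:
            raise ParameterError("refractory must be positive")
        if not 50.0 <= self.baseline_rate <= 560.0:
            raise ParameterError(
                "baseline_rate outside the observed multi-unit range [50, 560] Hz"
            )
        if self.noise_sigma <= 0:
            raise ParameterError("noise_sigma must be positive")


def make_default_song_model(seed: int = 0) -> SongModel:
    """A small Bengalese-finch-like song model.

    The motif is a -> b -> c -> x, where x is a branch point resolving to y
    (p = 0.7) or z (p = 0.3), both of which lead into a repeat-type
    syllable j (continuation probability 0.75, mean run length 4). Three
    stack syllables carry a 1% pitch c.v. so condition effects on pitch are
    measurable at the scale reported for carbachol. ``seed`` is accepted
    for interface symmetry; the default model is parametric, so any seed
    yields the identical model.
    """
    del seed  # the default model carries no sampled state
    t = dict(
        a=SyllableTemplate("a", "stack", f0=700.0, duration=0.090,
                           pitch_cv=0.010, duration_cv=0.030, amplitude_cv=0.050),
        b=SyllableTemplate("b", "sweep", f0=1500.0, duration=0.070,
                           duration_cv=0.030, amplitude_cv=0.050),
        c=SyllableTemplate("c", "stack", f0=600.0, duration=0.080,
                           pitch_cv=0.010, duration_cv=0.030, amplitude_cv=0.050),
        x=SyllableTemplate("x", "complex", f0=800.0, duration=0.080,
                           duration_cv=0.030, amplitude_cv=0.050),
        y=SyllableTemplate("y", "stack", f0=900.0, duration=0.060,
                           pitch_cv=0.010, duration_cv=0.030, amplitude_cv=0.050),
        z=SyllableTemplate("z", "noisy", f0=4000.0, duration=0.060,
                           duration_cv=0.030, amplitude_cv=0.050),
        j=SyllableTemplate("j", "stack", f0=750.0, duration=0.050,
                           pitch_cv=0.010, duration_cv=0.030, amplitude_cv=0.050),
    )
    transitions = {
        "a": {"b": 1.0},
        "b": {"c": 1.0},
        "c": {"x": 1.0},
        "x": {"y": 0.7, "z": 0.3},
        "y": {"j": 1.0},
        "z": {"j": 1.0},
        "j": {END: 1.0},
    }
    return SongModel(
        templates=t,
        transitions=transitions,
        start_label="a",
        repeat_params={"j": 0.75},
    )


def make_default_neural_model() -> NeuralModel:
    """A site with onset-locked premotor and postmotor rate bumps."""
    profile = RateProfile(
        baseline=150.0,
        bumps=((-0.020, 0.010, 120.0), (0.030, 0.008, 80.0)),
    )
    return NeuralModel(rate_template=profile, baseline_rate=150.0)


def apply_condition(model: SongModel, deltas: ConditionDeltas) -> SongModel:
    """Return a new model with the condition effects applied.

    Fundamental frequencies are multiplied by ``1 + pitch_shift``, pitch
    c.v. by ``pitch_cv_scale``, syllable durations, gap mean, and
    amplitudes by their respective ``1 + shift`` factors; transition rows
    and repeat continuation probabilities are offset and validated.
    """
    templates = {
        label: replace(
            tpl,
            f0=tpl.f0 * (1.0 + deltas.pitch_shift),
            pitch_cv=tpl.pitch_cv * deltas.pitch_cv_scale,
            duration=tpl.duration * (1.0 + deltas.syllable_duration_shift),
            ramp=tpl.ramp * (1.0 + deltas.syllable_duration_shift),
            base_amplitude=tpl.base_amplitude * (1.0 + deltas.amplitude_shift),
        )
        for label, tpl in model.templates.items()
    }
    transitions: dict[str, dict[str, float]] = {}
    for label, row in model.transitions.items():
        shift = deltas.transition_shift.get(label, {})
        new_row = {out: p + shift.get(out, 0.0) for out, p in row.items()}
        for out, p in new_row.items():
            if p < -1e-12 or p > 1 + 1e-12:
                raise ParameterError(
                    f"shifted probability {p:.6g} for {label!r}->{out!r} "
                    "leaves [0, 1]"
                )
        total = sum(new_row.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"shifted transition row for {label!r} sums to {total}, not 1"
            )
        transitions[label] = {
            out: min(1.0, max(0.0, p)) / total for out, p in new_row.items()
        }
    repeat_params = {}
    for label, p in model.repeat_params.items():
        q = p + deltas.repeat_continuation_shift
        if not 0 <= q < 1:
            raise ParameterError(
                f"shifted continuation probability {q:.6g} for {label!r} "
                "leaves [0, 1)"
            )
        repeat_params[label] = q
    return replace(
        model,
        templates=templates,
        transitions=transitions,
        repeat_params=repeat_params,
        gap_mean=model.gap_mean * (1.0 + deltas.gap_duration_shift),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative jitter with unit mean and the given c.v."""
    if cv <= 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-s2 / 2, sigma=math.sqrt(s2)))


def _gamma_gap(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def _raised_cosine_env(n: int, ramp_n: int) -> np.ndarray:
    env = np.ones(n)
    ramp_n = min(ramp_n, n // 2)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[-ramp_n:] = r[::-1]
    return env


def _render_syllable(
    tpl: SyllableTemplate,
    f0: float,
    duration: float,
    amplitude: float,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one syllable; mid-syllable RMS equals ``amplitude``."""
    n = max(8, int(round(duration * rate)))
    t = np.arange(n) / rate
    if tpl.kind == "noisy":
        x = rng.standard_normal(n)
        sos = signal.butter(4, [2000.0, 8000.0], btype="bandpass", fs=rate, output="sos")
        x = signal.sosfiltfilt(sos, x)
        x *= amplitude / np.sqrt(np.mean(x**2))
    else:
        if tpl.kind == "stack":
            f_inst = np.full(n, f0)
        elif tpl.kind == "sweep":
            f_inst = f0 * (1.0 + 0.25 * t / duration)  # linear FM, +25% across
        else:  # complex: constant-frequency half, then a linear sweep
            f_inst = np.where(
                t < duration / 2,
                f0,
                f0 * (1.0 + 0.5 * (t - duration / 2) / duration),
            )
        phase = 2 * np.pi * np.cumsum(f_inst) / rate
        amps = tpl.harmonic_rolloff ** np.arange(tpl.n_harmonics)
        x = np.zeros(n)
        nyq = rate / 2
        for h, a in enumerate(amps, start=1):
            if (h * np.max(f_inst)) >= nyq:
                break
            x += a * np.sin(h * phase)
        rms = np.sqrt(np.sum(amps**2) / 2)
        x *= amplitude / rms
    return x * _raised_cosine_env(n, int(round(tpl.ramp * rate)))


def _sample_elements(
    model: SongModel, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """One bout's element sequence as (label, run_length) pairs."""
    elements: list[tuple[str, int]] = []
    label = model.start_label
    while label != END:
        run = 1
        cont = model.repeat_params.get(label, 0.0)
        if cont > 0:
            run = int(rng.geometric(1.0 - cont))
        elements.append((label, run))
        row = model.transitions[label]
        outs = list(row)
        probs = np.array([row[o] for o in outs])
        label = outs[rng.choice(len(outs), p=probs / probs.sum())]
    return elements


def synthesize_bouts(
    model: SongModel,
    n_bouts: int,
    seed: int,
    condition: str = "baseline",
) -> tuple[list[Waveform], pd.DataFrame, pd.DataFrame]:
    """Render ``n_bouts`` song bouts with ground truth.

    Returns one waveform per bout, an annotation table
    (``bout_id, rendition, label, onset_s, offset_s, condition``) with exact
    half-open syllable intervals, and a truth table that additionally
    stores the drawn per-rendition ``f0_hz``, ``amplitude``, ``duration_s``,
    ``gap_before_s``, and the within-bout ``element_index``. Background
    Gaussian noise at the model's ``noise_floor`` RMS is added to every
    bout. Deterministic given ``seed``.
    """
    if n_bouts < 1:
        raise ParameterError("n_bouts must be >= 1")
    rng = np.random.default_rng(seed)
    waveforms: list[Waveform] = []
    rows: list[dict] = []
    rendition_counter: dict[str, int] = {}
    rate = model.sample_rate
    for bout_id in range(n_bouts):
        elements = _sample_elements(model, rng)
        pieces: list[np.ndarray] = []
        cursor = model.pad
        pieces.append(np.zeros(int(round(model.pad * rate))))
        prev_gap = float("nan")
        for element_index, (label, run) in enumerate(elements):
            tpl = model.templates[label]
            for pos in range(run):
                f0 = tpl.f0 * _lognormal_factor(rng, tpl.pitch_cv)
                dur = tpl.duration * _lognormal_factor(rng, tpl.duration_cv)
                amp = tpl.base_amplitude * _lognormal_factor(rng, tpl.amplitude_cv)
                x = _render_syllable(tpl, f0, dur, amp, rate, rng)
                onset = cursor
                offset = cursor + x.size / rate
                rendition = rendition_counter.get(label, 0)
                rendition_counter[label] = rendition + 1
                rows.append(
                    dict(
                        bout_id=bout_id,
                        rendition=rendition,
                        label=label,
                        onset_s=onset,
                        offset_s=offset,
                        condition=condition,
                        f0_hz=f0 if tpl.kind != "noisy" else float("nan"),
                        amplitude=amp,
                        duration_s=x.size / rate,
                        gap_before_s=prev_gap,
                        element_index=element_index,
                        run_length=run,
                        run_position=pos,
                    )
                )
                pieces.append(x)
                cursor = offset
                gap = _gamma_gap(rng, model.gap_mean, model.gap_cv)
                pieces.append(np.zeros(int(round(gap * rate))))
                prev_gap = gap
                cursor += int(round(gap * rate)) / rate
        pieces.append(np.zeros(int(round(model.pad * rate))))
        samples = np.concatenate(pieces)
        if model.noise_floor > 0:
            samples = samples + rng.normal(0.0, model.noise_floor, samples.size)
        waveforms.append(Waveform(samples, rate))
    truth = pd.DataFrame(rows)
    annotations = truth[
        ["bout_id", "rendition", "label", "onset_s", "offset_s", "condition"]
    ].copy()
    return waveforms, annotations, truth


def generate_spike_renditions(
    nm: NeuralModel,
    deltas: ConditionDeltas,
    n_renditions: int,
    window: tuple[float, float],
    seed: int,
    label: str = "",
    condition: str = "baseline",
) -> tuple[AlignedRaster, RateProfile]:
    """Inhomogeneous-Poisson spike renditions aligned to syllable onset.

    Spikes are drawn by thinning a homogeneous Poisson process at the peak
    of ``(1 + rate_gain) * rate_template`` over the window, then enforcing
    the refractory period (earlier spike kept). Returns the raster and the
    effective (gain-scaled) rate profile as ground truth.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ParameterError("window start must precede end")
    if n_renditions < 1:
        raise ParameterError("n_renditions must be >= 1")
    gain = 1.0 + deltas.rate_gain
    profile = nm.rate_template
    true_profile = RateProfile(
        baseline=profile.baseline * gain,
        bumps=tuple((c, sd, a * gain) for c, sd, a in profile.bumps),
    )
    rmax = true_profile.max_rate(window)
    rng = np.random.default_rng(seed)
    span = t1 - t0
    trains: list[np.ndarray] = []
    for _ in range(n_renditions):
        if rmax <= 0:
            trains.append(np.empty(0))
            continue
        n = rng.poisson(rmax * span)
        cand = np.sort(rng.uniform(t0, t1, n))
        keep = rng.uniform(0.0, 1.0, n) < true_profile(cand) / rmax
        times = cand[keep]
        trains.append(_enforce_refractory(times, nm.refractory))
    raster = AlignedRaster(window=window, trains=trains, label=label, condition=condition)
    return raster, true_profile


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    if times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def spike_waveform_template(nm: NeuralModel) -> np.ndarray:
    """1 ms biphasic (negative-first) template; minimum at -peak*sigma."""
    n = int(round(0.001 * nm.sample_rate))
    t = np.arange(n) / nm.sample_rate
    shape = -np.exp(-0.5 * ((t - 0.0003) / 0.0001) ** 2) + 0.45 * np.exp(
        -0.5 * ((t - 0.00065) / 0.00015) ** 2
    )
    shape /= -shape.min()  # unit negative peak
    return shape * nm.spike_peak_sigma * nm.noise_sigma


def render_voltage_trace(
    spike_times,
    nm: NeuralModel,
    duration: float,
    seed: int,
) -> Waveform:
    """Gaussian noise plus a biphasic spike waveform at each spike time.

    The template's negative peak is aligned to each spike time. Overlap
    beyond the refractory period is the caller's responsibility.
    """
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() >= duration):
        raise ParameterError("all spike times must lie in [0, duration)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * nm.sample_rate))
    trace = rng.normal(0.0, nm.noise_sigma, n)
    template = spike_waveform_template(nm)
    peak_idx = int(np.argmin(template))
    for t in spike_times:
        i0 = int(round(t * nm.sample_rate)) - peak_idx
        j0, j1 = max(0, i0), min(n, i0 + template.size)
        trace[j0:j1] += template[j0 - i0 : j1 - i0]
    return Waveform(trace, nm.sample_rate)
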