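import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songphys import audio, effects
from songphys.audio import (
    Envelope,
    SpectrogramParams,
    SyllableEvent,
    Waveform,
    coefficient_of_variation,
    compute_envelope,
    compute_spectrogram,
    extract_pitch_contour,
    measure_durations,
    measure_syllable_amplitude,
    measure_syllable_pitch,
    remove_outliers,
    segment_syllables,
)
from songphys.errors import DataError, ParameterError

RATE = 32000.0


def sine(freq, duration, amplitude=1.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)


class TestWaveform:
    def test_rejects_nonfinite(self):
        with pytest.raises(ParameterError):
            Waveform(np.array([0.0, np.nan]), RATE)

    def test_rejects_bad_rate(self):
        with pytest.raises(ParameterError):
            Waveform(np.zeros(10), 0.0)

    def test_segment_is_half_open(self):
        w = Waveform(np.arange(10, dtype=float), 10.0)
        assert w.segment(0.2, 0.5).samples.tolist() == [2.0, 3.0, 4.0]


class TestComputeEnvelope:
    def test_dc_rejected(self):
        # an 81-tap FIR at 32 kHz leaves ~ -23 dB at DC; the envelope of a
        # unit DC input must be strongly attenuated relative to passband
        w = Waveform(np.ones(8000), RATE)
        env = compute_envelope(w)
        assert np.max(env.values[500:-500]) < 0.1
        passband = compute_envelope(sine(2000.0, 0.25)).values[2000:-2000]
        assert np.max(env.values[500:-500]) < 0.15 * np.max(passband)

    def test_sine_rms(self):
        # a sine of amplitude A has envelope A/sqrt(2); measured at 3 kHz,
        # inside the flat passband (the 81-tap filter's transition around the
        # 500 Hz edge spans beyond 1 kHz, attenuating the spec's 1 kHz tone)
        w = sine(3000.0, 0.5, amplitude=0.8)
        env = compute_envelope(w)
        interior = env.values[2000:-2000]
        assert np.allclose(interior, 0.8 / np.sqrt(2), rtol=0.01)

    def test_silence(self):
        env = compute_envelope(Waveform(np.zeros(6000), RATE))
        assert np.all(env.values == 0)

    def test_band_outside_nyquist(self):
        with pytest.raises(ParameterError):
            compute_envelope(sine(1000, 0.1), band=(500.0, 20000.0))

    def test_amplitude_linearity(self):
        w1 = sine(2000.0, 0.2, amplitude=1.0)
        w3 = Waveform(3.0 * w1.samples, RATE)
        e1 = compute_envelope(w1).values[2000:-2000]
        e3 = compute_envelope(w3).values[2000:-2000]
        assert np.allclose(e3, 3.0 * e1, rtol=0.005)


class TestSegmentSyllables:
    def test_rectangular_pulse(self):
        values = np.zeros(int(0.3 * RATE))
        values[int(0.100 * RATE) : int(0.180 * RATE)] = 1.0
        events = segment_syllables(Envelope(values, RATE), threshold=0.5)
        assert len(events) == 1
        assert events[0].onset == pytest.approx(0.100, abs=1.5 / RATE)
        assert events[0].offset == pytest.approx(0.180, abs=1.5 / RATE)

    def test_short_gap_merged(self):
        values = np.zeros(int(0.3 * RATE))
        values[int(0.10 * RATE) : int(0.14 * RATE)] = 1.0
        values[int(0.142 * RATE) : int(0.18 * RATE)] = 1.0  # 2 ms gap
        events = segment_syllables(Envelope(values, RATE), 0.5, min_gap=0.005)
        assert len(events) == 1

    def test_short_event_dropped(self):
        values = np.zeros(int(0.1 * RATE))
        values[100:150] = 1.0  # ~1.6 ms
        assert segment_syllables(Envelope(values, RATE), 0.5) == []

    def test_threshold_must_be_positive(self):
        with pytest.raises(ParameterError):
            segment_syllables(Envelope(np.zeros(100), RATE), 0.0)

    def test_synthetic_onsets_within_2ms(self, default_model, default_bouts):
        waveforms, annotations, _ = default_bouts
        errors = []
        for bout_id, bout_ann in annotations.groupby("bout_id"):
            env = compute_envelope(waveforms[int(bout_id)])
            thresh = effects._auto_threshold(env, bout_ann, 10.0)
            events = segment_syllables(env, thresh)
            for _, row in bout_ann.iterrows():
                overlaps = [
                    (min(ev.offset, row.offset_s) - max(ev.onset, row.onset_s), ev)
                    for ev in events
                ]
                ov, best = max(overlaps, key=lambda t: t[0])
                errors.append(abs(best.onset - row.onset_s) if ov > 0 else np.inf)
        errors = np.asarray(errors)
        assert np.mean(errors < 0.002) >= 0.95


class TestSpectrogram:
    def test_pure_tone_peak_bin(self):
        spec = compute_spectrogram(sine(1000.0, 0.1))
        peak_bins = np.argmax(spec.power, axis=0)
        expected = int(round(1000.0 / spec.df))
        assert np.all(np.abs(peak_bins - expected) <= 1)

    def test_parseval(self, rng):
        x = rng.standard_normal(4096)
        w = Waveform(x, RATE)
        p = SpectrogramParams(fft_size=1024)
        spec = compute_spectrogram(w, p)
        win = np.exp(
            -0.5 * ((np.arange(1024) - 1023 / 2) / (p.window_sd * RATE)) ** 2
        )
        # reconstruct full-spectrum power from the one-sided result
        full = 2 * spec.power.sum(axis=0) - spec.power[0] - spec.power[-1]
        for j, col_energy in enumerate(full):
            frame = x[j * 4 : j * 4 + 1024] * win
            assert col_energy == pytest.approx(1024 * np.sum(frame**2), rel=0.01)

    def test_column_spacing(self):
        spec = compute_spectrogram(sine(1000.0, 0.2))
        assert np.allclose(np.diff(spec.times), 4 / RATE)  # 0.125 ms at 32 kHz

    def test_too_short_input(self):
        with pytest.raises(DataError):
            compute_spectrogram(Waveform(np.zeros(512), RATE))

    def test_bin_width(self):
        spec = compute_spectrogram(sine(1000.0, 0.1), SpectrogramParams())
        assert spec.df == pytest.approx(31.25)

    def test_window_sd_range_enforced(self):
        with pytest.raises(ParameterError):
            SpectrogramParams(window_sd=0.005)


class TestPitchContour:
    def test_on_bin_center_delta_near_zero(self):
        f0 = 32 * 31.25  # exactly bin 32
        spec = compute_spectrogram(sine(f0, 0.1))
        contour = extract_pitch_contour(spec, (f0 - 100, f0 + 100))
        assert np.allclose(contour.pitch, f0, atol=0.05)

    def test_against_zero_padded_fft_oracle(self):
        # oracle: 16x zero-padded FFT peak on the same frames
        f0 = 700.0
        t = np.arange(int(0.1 * RATE)) / RATE
        x = sum(0.6**k * np.sin(2 * np.pi * (k + 1) * f0 * t) for k in range(5))
        w = Waveform(x, RATE)
        p = SpectrogramParams()
        spec = compute_spectrogram(w, p)
        contour = extract_pitch_contour(spec, (600.0, 800.0))
        win = np.exp(
            -0.5 * ((np.arange(1024) - 1023 / 2) / (p.window_sd * RATE)) ** 2
        )
        oracle = []
        for j in range(0, spec.power.shape[1], 50):
            frame = x[j * 4 : j * 4 + 1024] * win
            big = np.abs(np.fft.rfft(frame, n=16 * 1024))
            f = np.fft.rfftfreq(16 * 1024, 1 / RATE)
            sel = (f >= 600) & (f <= 800)
            oracle.append(f[sel][np.argmax(big[sel])])
        assert 699.0 <= np.mean(contour.pitch) <= 701.0
        assert np.mean(oracle) == pytest.approx(np.mean(contour.pitch), abs=1.0)

    @pytest.mark.parametrize("f0", [600.0, 700.0, 900.0])
    def test_stack_accuracy_within_0p1_percent(self, f0):
        t = np.arange(int(0.08 * RATE)) / RATE
        x = sum(0.6**k * np.sin(2 * np.pi * (k + 1) * f0 * t) for k in range(5))
        spec = compute_spectrogram(Waveform(x, RATE))
        contour = extract_pitch_contour(spec, (0.9 * f0, 1.1 * f0))
        measured = measure_syllable_pitch(contour, (0.01, 0.07))
        assert abs(measured - f0) <= 0.001 * f0

    def test_band_needs_three_bins(self):
        spec = compute_spectrogram(sine(1000.0, 0.1))
        with pytest.raises(ParameterError):
            extract_pitch_contour(spec, (1000.0, 1030.0))

    def test_edge_peak_flagged(self):
        spec = compute_spectrogram(sine(1000.0, 0.1))
        contour = extract_pitch_contour(spec, (1100.0, 1300.0))
        assert contour.edge.all()  # true peak lies below the band


class TestMeasureSyllablePitch:
    def test_constant_contour(self):
        c = audio.PitchContour(times=np.linspace(0, 0.1, 20), pitch=np.full(20, 700.0))
        assert measure_syllable_pitch(c, (0.0, 0.1)) == 700.0

    def test_three_point_mean(self):
        c = audio.PitchContour(
            times=np.array([0.01, 0.02, 0.03]), pitch=np.array([690.0, 700.0, 710.0])
        )
        assert measure_syllable_pitch(c, (0.0, 0.05)) == pytest.approx(700.0)

    def test_empty_overlap_is_nan(self):
        c = audio.PitchContour(times=np.array([0.01]), pitch=np.array([700.0]))
        assert np.isnan(measure_syllable_pitch(c, (0.5, 0.6)))


class TestMeasureSyllableAmplitude:
    def test_constant_envelope(self):
        env = Envelope(np.full(3200, 0.7), RATE)
        ev = SyllableEvent(onset=0.01, offset=0.09)
        assert measure_syllable_amplitude(env, ev) == pytest.approx(0.7)

    def test_triangular_envelope(self):
        # symmetric triangle peaking at 1: mean over the middle 80% is 0.6
        n = 32000
        ev = SyllableEvent(onset=0.0, offset=1.0)
        x = np.arange(n) / n
        env = Envelope(1.0 - np.abs(2 * x - 1), 32000.0)
        assert measure_syllable_amplitude(env, ev) == pytest.approx(0.6, abs=1e-3)

    def test_zero_envelope(self):
        env = Envelope(np.zeros(3200), RATE)
        assert measure_syllable_amplitude(env, SyllableEvent(0.01, 0.09)) == 0.0

    def test_too_short_event(self):
        env = Envelope(np.ones(3200), RATE)
        with pytest.raises(DataError):
            measure_syllable_amplitude(env, SyllableEvent(0.01, 0.01005))


class TestMeasureDurations:
    def test_onset_to_onset(self):
        bout = [SyllableEvent(0.000, 0.080, "a"), SyllableEvent(0.300, 0.380, "b")]
        seq, _, _ = measure_durations(bout, ["a", "b"])
        assert seq == [pytest.approx(0.300)]

    def test_gap(self):
        bout = [SyllableEvent(0.0, 0.08, "a"), SyllableEvent(0.12, 0.2, "b")]
        _, _, gaps = measure_durations(bout, ["a", "b"])
        assert gaps == [pytest.approx(0.04)]

    def test_no_match_is_empty(self):
        bout = [SyllableEvent(0.0, 0.08, "a")]
        assert measure_durations(bout, ["a", "b"]) == ([], [], [])

    def test_multiple_matches(self):
        bout = [
            SyllableEvent(0.0, 0.05, "a"),
            SyllableEvent(0.1, 0.15, "b"),
            SyllableEvent(0.2, 0.25, "a"),
            SyllableEvent(0.3, 0.35, "b"),
        ]
        seq, syl, gaps = measure_durations(bout, ["a", "b"])
        assert len(seq) == 2 and len(syl) == 4 and len(gaps) == 2


class TestRemoveOutliers:
    def test_worked_example(self):
        out = remove_outliers([10, 11, 9, 10, 12, 50])
        assert sorted(out.tolist()) == [9, 10, 10, 11, 12]

    def test_identical_values_unchanged(self):
        out = remove_outliers([5.0] * 8)
        assert out.tolist() == [5.0] * 8

    def test_normal_sample_removal_below_3_percent(self, rng):
        x = rng.standard_normal(10000)
        out = remove_outliers(x)
        assert 1 - out.size / x.size < 0.03

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_output_subsequence_of_input(self, values):
        out = remove_outliers(values)
        values_left = list(values)
        for v in out:
            assert v in values_left
            values_left.remove(v)

    def test_near_idempotent_on_unimodal_data(self):
        failures = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(10.0, 1.0, 300)
            three = remove_outliers(x)
            four = remove_outliers(three, n_passes=1)
            failures += four.size != three.size
        assert failures <= 1  # idempotent in >= 99% of trials


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_worked_example(self):
        assert coefficient_of_variation([100, 102, 98, 101, 99]) == pytest.approx(
            0.0158114, abs=1e-6
        )

    @given(
        st.lists(st.floats(1.0, 1e4), min_size=2, max_size=30).filter(
            lambda v: np.std(v) > 0
        ),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=50)
    def test_scale_invariance(self, values, c):
        base = coefficient_of_variation(values)
        scaled = coefficient_of_variation([c * v for v in values])
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_mean_errors(self):
        with pytest.raises(DataError):
            coefficient_of_variation([-1.0, 1.0])
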