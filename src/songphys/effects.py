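"""Experiment-level pipeline.

Ties the other modules together: analysis-window selection around an
infusion (or social-context) schedule, full feature extraction from
waveforms plus annotations, normalized treatment/baseline effect
summaries with outlier removal and inclusion rules, nonparametric paired
and unpaired comparisons, the additivity analysis for dual manipulations,
and a config-driven ``run_experiment`` entry point used by the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from songphys import audio, synth
from songphys.audio import (
    SpectrogramParams,
    SyllableEvent,
    Waveform,
    coefficient_of_variation,
    remove_outliers,
)
from songphys.errors import ConfigError, DataError, ParameterError

__all__ = [
    "AnalysisProtocol",
    "EffectEntry",
    "FeatureConfig",
    "select_analysis_windows",
    "normalized_feature_change",
    "amplitude_session_exclusion",
    "paired_comparison",
    "unpaired_comparison",
    "additivity_analysis",
    "extract_features",
    "summarize_effects",
    "config_for_model",
    "run_synthetic_experiment",
    "run_experiment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisProtocol:
    """Analysis-window definitions in minutes relative to infusion onset.

    ``standard``: a (by default two-hour) treatment window beginning one
    hour after infusion onset, with a baseline window immediately before
    onset. ``dual_drug``: a single one-hour window beginning at the later
    of the two estimated drug onsets.
    """

    baseline: tuple[float, float] = (-120.0, 0.0)
    treatment: tuple[float, float] = (60.0, 180.0)
    variant: str = "standard"

    def __post_init__(self) -> None:
        if self.variant not in ("standard", "dual_drug"):
            raise ParameterError("variant must be 'standard' or 'dual_drug'")
        if self.treatment[0] < 0:
            raise ParameterError("treatment window must start at or after onset")
        if self.baseline[1] > self.treatment[0]:
            raise ParameterError("baseline and treatment windows must not overlap")


@dataclass(frozen=True)
class EffectEntry:
    """One unit's normalized treatment/baseline change."""

    feature: str
    unit: str
    ratio: float
    pct_change: float
    n_base: int
    n_treat: int


def select_analysis_windows(
    schedule: dict, protocol: AnalysisProtocol
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Absolute (baseline, treatment) intervals in minutes.

    ``schedule`` must contain ``infusion_onset``; the ``dual_drug`` variant
    additionally requires ``estimated_onsets`` (both drugs), and its
    treatment window is the hour beginning at the later onset. Renditions
    are assigned to a window if their bout start time falls in the
    half-open interval.
    """
    if "infusion_onset" not in schedule:
        raise DataError("schedule is missing 'infusion_onset'")
    onset = float(schedule["infusion_onset"])
    baseline = (onset + protocol.baseline[0], onset + protocol.baseline[1])
    if protocol.variant == "dual_drug":
        onsets = schedule.get("estimated_onsets")
        if not onsets or len(onsets) < 2:
            raise DataError("dual_drug schedule requires two estimated onsets")
        start = float(max(onsets))
        treatment = (start, start + 60.0)
    else:
        treatment = (onset + protocol.treatment[0], onset + protocol.treatment[1])
    return baseline, treatment


def in_window(times, interval: tuple[float, float]) -> np.ndarray:
    """Half-open membership mask for rendition/bout start times."""
    t = np.asarray(times, dtype=float)
    return (t >= interval[0]) & (t < interval[1])


def normalized_feature_change(
    base,
    treat,
    feature: str = "",
    unit: str = "",
    kind: str = "mean",
    min_n: int = 15,
) -> EffectEntry | None:
    """Ratio-of-means (or ratio-of-c.v.s) treatment/baseline change.

    Inputs are expected to be outlier-cleaned already. Returns ``None``
    (unit excluded, not an error) when either condition has fewer than
    ``min_n`` values.
    """
    base = np.asarray(base, dtype=float)
    treat = np.asarray(treat, dtype=float)
    base = base[np.isfinite(base)]
    treat = treat[np.isfinite(treat)]
    if base.size < min_n or treat.size < min_n:
        return None
    if kind == "mean":
        ratio = float(treat.mean() / base.mean())
    elif kind == "cv":
        ratio = coefficient_of_variation(treat) / coefficient_of_variation(base)
    else:
        raise ParameterError("kind must be 'mean' or 'cv'")
    return EffectEntry(
        feature=feature,
        unit=unit,
        ratio=ratio,
        pct_change=100.0 * (ratio - 1.0),
        n_base=base.size,
        n_treat=treat.size,
    )


def amplitude_session_exclusion(per_syllable_changes) -> bool:
    """True when every syllable's amplitude changed by > 25% with the same
    sign (likely a microphone-orientation artifact)."""
    changes = np.asarray(per_syllable_changes, dtype=float)
    if changes.size == 0:
        raise DataError("no per-syllable changes provided")
    if np.any(np.abs(changes) <= 25.0):
        return False
    return bool(np.all(changes > 25.0) or np.all(changes < -25.0))


def paired_comparison(a, b, sidedness: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for matched samples.

    Uses the exact null distribution for up to 25 informative (nonzero)
    differences and the normal approximation otherwise. All differences
    zero gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ParameterError("paired comparison needs equal-length samples, n >= 2")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, alternative=sidedness, method=method, zero_method="wilcox"
    )
    return float(res.pvalue)


def unpaired_comparison(a, b, sidedness: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value; exact for small untied
    samples, tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ParameterError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=sidedness, method="auto")
    return float(res.pvalue)


def additivity_analysis(e_a, e_b, e_ab) -> tuple[float, float]:
    """Deviation of a combined manipulation from the sum of its parts.

    Per matched unit, residual = e_ab - (e_a + e_b); returns the mean
    residual and a two-tailed signed-rank p-value of the residuals
    against zero.
    """
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    e_ab = np.asarray(e_ab, dtype=float)
    if not (e_a.size == e_b.size == e_ab.size):
        raise DataError("units must be matched across all three conditions")
    residuals = e_ab - (e_a + e_b)
    if np.all(residuals == 0):
        return 0.0, 1.0
    p = paired_comparison(residuals, np.zeros_like(residuals))
    return float(residuals.mean()), p


# ---------------------------------------------------------------------------
# feature-extraction pipeline


@dataclass(frozen=True)
class FeatureConfig:
    """Settings for the waveform -> feature-table pipeline.

    ``stack_f0`` maps harmonic-stack labels (the only labels measured for
    pitch) to their expected baseline fundamental; the pitch search band is
    ``+/- pitch_band_frac`` around it. ``threshold`` of ``None`` selects
    the automatic rule: ``threshold_mult`` times the median envelope
    outside annotated syllables.
    """

    stack_f0: dict[str, float] = field(default_factory=dict)
    sequence_spec: tuple[str, ...] | None = None
    band: tuple[float, float] = (500.0, 10000.0)
    fir_order: int = 80
    smooth: float = 0.0025
    spectro: SpectrogramParams = field(default_factory=SpectrogramParams)
    threshold: float | None = None
    threshold_mult: float = 10.0
    min_syllable: float = 0.005
    min_gap: float = 0.005
    pitch_band_frac: float = 0.10
    measure_window: tuple[float, float] = (0.4, 0.6)
    min_renditions: int = 15


def config_for_model(
    model: synth.SongModel,
    sequence_spec: Sequence[str] | None = None,
    **overrides,
) -> FeatureConfig:
    """Derive a pipeline config from a (baseline) song model."""
    stack_f0 = {
        label: tpl.f0
        for label, tpl in model.templates.items()
        if tpl.kind == "stack"
    }
    spec = tuple(sequence_spec) if sequence_spec else None
    return FeatureConfig(stack_f0=stack_f0, sequence_spec=spec, **overrides)


def _auto_threshold(
    env: audio.Envelope, bout_annotations: pd.DataFrame, mult: float
) -> float:
    mask = np.ones(env.values.size, dtype=bool)
    for _, row in bout_annotations.iterrows():
        i0 = max(0, int(row["onset_s"] * env.rate))
        i1 = min(mask.size, int(np.ceil(row["offset_s"] * env.rate)))
        mask[i0:i1] = False
    floor = np.median(env.values[mask]) if mask.any() else np.median(env.values)
    if floor <= 0:
        floor = max(env.values.max() * 1e-4, np.finfo(float).tiny)
    return float(mult * floor)


def _match_events(
    events: list[SyllableEvent], bout_annotations: pd.DataFrame
) -> list[tuple[pd.Series, SyllableEvent] | tuple[pd.Series, None]]:
    """Pair each annotated syllable with the detected event of max overlap."""
    matched = []
    for _, row in bout_annotations.iterrows():
        best, best_ov = None, 0.0
        for ev in events:
            ov = min(ev.offset, row["offset_s"]) - max(ev.onset, row["onset_s"])
            if ov > best_ov:
                best, best_ov = ev, ov
        matched.append((row, best))
    return matched


def extract_features(
    waveforms: Sequence[Waveform],
    annotations: pd.DataFrame,
    cfg: FeatureConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full acoustic pipeline over a set of annotated bouts.

    For every annotated syllable: segment the bout's RMS envelope by
    amplitude threshold, take the detected event with maximal overlap,
    measure its duration and middle-80% envelope amplitude, and — for
    harmonic-stack labels — its pitch from a parabolic-interpolated
    spectral-peak contour averaged over the configured fraction of the
    syllable. Returns the feature table plus a list of exclusion reasons
    for annotations with no matching detected event.
    """
    records: list[dict] = []
    exclusions: list[str] = []
    envelopes: dict[int, audio.Envelope] = {}
    for bout_id, bout_ann in annotations.groupby("bout_id", sort=True):
        w = waveforms[int(bout_id)]
        env = audio.compute_envelope(w, band=cfg.band, fir_order=cfg.fir_order,
                                     smooth=cfg.smooth)
        envelopes[int(bout_id)] = env
        thresh = cfg.threshold or _auto_threshold(env, bout_ann, cfg.threshold_mult)
        events = audio.segment_syllables(
            env, thresh, min_syllable=cfg.min_syllable, min_gap=cfg.min_gap
        )
        for row, ev in _match_events(events, bout_ann):
            if ev is None:
                exclusions.append(
                    f"bout {bout_id} {row['label']} rendition {row['rendition']}: "
                    "no detected event overlaps the annotation"
                )
                continue
            try:
                amp = audio.measure_syllable_amplitude(env, ev)
            except DataError as exc:
                exclusions.append(
                    f"bout {bout_id} {row['label']} rendition "
                    f"{row['rendition']}: {exc}"
                )
                continue
            records.append(
                dict(
                    bout_id=int(bout_id),
                    rendition=int(row["rendition"]),
                    label=row["label"],
                    pitch_hz=float("nan"),
                    amplitude=amp,
                    duration_s=ev.duration,
                    onset_s=ev.onset,
                    offset_s=ev.offset,
                    condition=row["condition"],
                )
            )
    feats = pd.DataFrame(records)
    if feats.empty:
        return feats, exclusions

    # second pass: pitch for stack-type labels, using a measurement window
    # placed at a fixed fraction of the label's median detected duration
    for label, f0 in cfg.stack_f0.items():
        sel = feats["label"] == label
        if not sel.any():
            continue
        med_dur = float(feats.loc[sel, "duration_s"].median())
        w0 = cfg.measure_window[0] * med_dur
        w1 = cfg.measure_window[1] * med_dur
        band = (f0 * (1 - cfg.pitch_band_frac), f0 * (1 + cfg.pitch_band_frac))
        for idx in feats.index[sel]:
            rec = feats.loc[idx]
            w = waveforms[int(rec["bout_id"])]
            seg = w.segment(rec["onset_s"], rec["offset_s"])
            try:
                spec = audio.compute_spectrogram(seg, cfg.spectro)
            except DataError:
                exclusions.append(
                    f"bout {int(rec['bout_id'])} {label} rendition "
                    f"{int(rec['rendition'])}: too short for spectrogram"
                )
                continue
            contour = audio.extract_pitch_contour(spec, band)
            feats.loc[idx, "pitch_hz"] = audio.measure_syllable_pitch(
                contour, (w0, w1)
            )
    return feats, exclusions


def _sequence_durations(
    feats: pd.DataFrame, sequence_spec: Sequence[str]
) -> np.ndarray:
    durs: list[float] = []
    for _, bout in feats.groupby("bout_id"):
        events = [
            SyllableEvent(
                onset=row["onset_s"],
                offset=row["offset_s"],
                label=row["label"],
                bout_id=int(row["bout_id"]),
            )
            for _, row in bout.sort_values("onset_s").iterrows()
        ]
        seq, _, _ = audio.measure_durations(events, list(sequence_spec))
        durs.extend(seq)
    return np.asarray(durs)


def summarize_effects(
    feats_base: pd.DataFrame,
    feats_treat: pd.DataFrame,
    cfg: FeatureConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-unit normalized treatment/baseline effect entries.

    Features: per-stack-label pitch and pitch c.v. (after the iterated
    4xMAD outlier rule), per-label amplitude, and — when a sequence spec is
    configured — onset-to-onset sequence duration. Units failing the
    minimum-rendition rule are logged as excluded.
    """
    entries: list[EffectEntry] = []
    exclusions: list[str] = []

    def _clean(values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        return remove_outliers(values) if values.size else values

    def _add(feature, unit, base, treat, kind="mean"):
        entry = normalized_feature_change(
            base, treat, feature=feature, unit=unit, kind=kind,
            min_n=cfg.min_renditions,
        )
        if entry is None:
            exclusions.append(
                f"{feature}/{unit}: fewer than {cfg.min_renditions} renditions "
                "in a condition"
            )
        else:
            entries.append(entry)

    for label in sorted(cfg.stack_f0):
        base = _clean(feats_base.loc[feats_base["label"] == label, "pitch_hz"])
        treat = _clean(feats_treat.loc[feats_treat["label"] == label, "pitch_hz"])
        if base.size == 0 and treat.size == 0:
            continue
        _add("pitch", label, base, treat)
        _add("pitch_cv", label, base, treat, kind="cv")

    labels = sorted(set(feats_base["label"]) | set(feats_treat["label"]))
    for label in labels:
        base = _clean(feats_base.loc[feats_base["label"] == label, "amplitude"])
        treat = _clean(feats_treat.loc[feats_treat["label"] == label, "amplitude"])
        _add("amplitude", label, base, treat)

    if cfg.sequence_spec:
        unit = "->".join(cfg.sequence_spec)
        base = _sequence_durations(feats_base, cfg.sequence_spec)
        treat = _sequence_durations(feats_treat, cfg.sequence_spec)
        if base.size and treat.size:
            _add("sequence_duration", unit, _clean(base), _clean(treat))
        else:
            exclusions.append(f"sequence_duration/{unit}: motif never matched")

    summary = pd.DataFrame([vars(e) for e in entries])
    return summary, exclusions


# ---------------------------------------------------------------------------
# config-driven experiment


def _deltas_from_config(spec: dict | None) -> synth.ConditionDeltas:
    if spec is None:
        return synth.ConditionDeltas()
    if spec == "carbachol":
        return synth.ConditionDeltas.carbachol()
    try:
        return synth.ConditionDeltas(**spec)
    except TypeError as exc:
        raise ConfigError(f"bad deltas specification: {exc}") from exc


def run_synthetic_experiment(
    model: synth.SongModel,
    deltas: synth.ConditionDeltas,
    n_bouts: int,
    seed: int,
    sequence_spec: Sequence[str] | None = None,
    cfg: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthesize baseline + treatment song and run the full pipeline.

    Baseline and treatment bouts are generated with independent child
    seeds; the treatment model is the baseline model with ``deltas``
    applied. Returns the per-unit effect summary and the exclusion log.
    """
    cfg = cfg or config_for_model(model, sequence_spec=sequence_spec)
    seeds = np.random.SeedSequence(seed).spawn(2)
    seed_base = int(seeds[0].generate_state(1)[0])
    seed_treat = int(seeds[1].generate_state(1)[0])
    treat_model = synth.apply_condition(model, deltas)
    wav_b, ann_b, _ = synth.synthesize_bouts(model, n_bouts, seed_base, "baseline")
    wav_t, ann_t, _ = synth.synthesize_bouts(
        treat_model, n_bouts, seed_treat, "treatment"
    )
    feats_b, exc_b = extract_features(wav_b, ann_b, cfg)
    feats_t, exc_t = extract_features(wav_t, ann_t, cfg)
    summary, exc_s = summarize_effects(feats_b, feats_t, cfg)
    return summary, exc_b + exc_t + exc_s


def run_experiment(config: dict | str | Path) -> dict:
    """Execute a config-described experiment and (optionally) write reports.

    The config mapping (or YAML file path) supports::

        seed: 1
        n_bouts: 60
        deltas: carbachol          # or a mapping of ConditionDeltas fields
        sequence_spec: [a, b, c]
        min_renditions: 15
        out_dir: reports/          # optional; CSV + JSON reports

    Returns ``{"summary": DataFrame, "exclusions": [...], "aggregate": {...}}``.
    Deterministic given the config.
    """
    if isinstance(config, (str, Path)):
        import yaml

        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    seed = int(config.get("seed", 0))
    n_bouts = int(config.get("n_bouts", 50))
    if n_bouts < 1:
        raise ConfigError("n_bouts must be >= 1")
    deltas = _deltas_from_config(config.get("deltas"))
    model = synth.make_default_song_model(seed)
    sequence_spec = config.get("sequence_spec", ["a", "b", "c"])
    cfg = config_for_model(
        model,
        sequence_spec=sequence_spec,
        min_renditions=int(config.get("min_renditions", 15)),
    )
    summary, exclusions = run_synthetic_experiment(
        model, deltas, n_bouts, seed, cfg=cfg
    )
    aggregate = {}
    for feature, grp in summary.groupby("feature"):
        ratios = grp["ratio"].to_numpy()
        agg = {
            "mean_pct_change": float(grp["pct_change"].mean()),
            "n_units": int(len(grp)),
        }
        if len(grp) >= 2:
            agg["p_vs_no_change"] = paired_comparison(ratios, np.ones_like(ratios))
        aggregate[feature] = agg
    result = {"summary": summary, "exclusions": exclusions, "aggregate": aggregate}
    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "effect_summary.csv", index=False)
        with open(out / "effect_summary.json", "w") as fh:
            json.dump(aggregate, fh, indent=2)
        with open(out / "exclusions.log", "w") as fh:
            fh.write("\n".join(exclusions) + ("\n" if exclusions else ""))
    return result
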