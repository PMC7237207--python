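# songphys

Quantitative analysis of birdsong and premotor multi-unit activity:
acoustic feature extraction (pitch, pitch variability, tempo, amplitude),
syllable-sequence statistics (branch-point transition tests, entropy,
repeats), and multi-unit neural analysis (spike detection, onset-aligned
rate traces, Fano factors) — together with seeded synthetic song/spike
generators so every stage of the pipeline can be validated end to end
against ground truth.

## Modules

| Module | Contents |
| --- | --- |
| `songphys.synth` | Song models (harmonic-stack / sweep / complex / noisy syllables, Markov sequencing with branch points and repeat runs), condition-effect injection, audio rendering with truth tables, inhomogeneous-Poisson spike renditions, voltage-trace rendering |
| `songphys.audio` | Band-passed RMS envelopes, amplitude-threshold segmentation, Gaussian-window spectrograms, parabolic-interpolation pitch contours, per-syllable pitch/amplitude/duration, iterated 4×MAD outlier rule, coefficient of variation |
| `songphys.sequence` | Repeat collapsing with the 200 ms gap rule, transition tables, generalized likelihood-ratio homogeneity test, transition-change magnitude, transition entropy, repeat-run statistics, Pearson correlation |
| `songphys.neural` | MAD/0.6745 noise estimation, negative-threshold spike detection, SNR, onset-aligned rasters, Gaussian-kernel rate traces, windowed counts / Fano factor, pair normalization and correlation, inclusion filtering |
| `songphys.effects` | Analysis-window selection, normalized treatment/baseline changes, session exclusion rules, signed-rank / rank-sum comparisons, additivity analysis, config-driven experiment runner |
| `songphys.recovery` | End-to-end parameter-recovery experiments used by the acceptance report |

## CLI

```sh
# synthesize annotated song bouts (WAV + annotations.csv + truth.csv)
songphys simulate-song --seed 1 --out-dir scratch/song

# extract per-rendition features from WAV + annotations
cat > scratch/features.yaml <<EOF
audio_dir: scratch/song
annotations: scratch/song/annotations.csv
stack_f0: {a: 700.0, c: 600.0, y: 900.0, j: 750.0}
sequence_spec: [a, b, c]
EOF
songphys features --config scratch/features.yaml --out-dir scratch/feat

# sequence statistics from an annotations CSV with two conditions
songphys sequence --config scratch/seq.yaml --out-dir scratch/seq

# synthetic voltage trace, then spike detection + rate statistics
songphys simulate-neural --seed 2 --out-dir scratch/neural
songphys neural --config scratch/neural.yaml --out-dir scratch/neural

# full synthetic baseline-vs-treatment experiment
songphys compare --config experiment.yaml --seed 3 --out-dir scratch/cmp
```

All subcommands take `--config` (YAML), `--seed`, `--out-dir`, and
`--log-level`. Exit codes: 0 success, 2 configuration error, 3 data error.

An experiment config for `compare` / `run_experiment`:

```yaml
seed: 1
n_bouts: 60
deltas: carbachol        # or a mapping, e.g. {pitch_shift: 0.012}
sequence_spec: [a, b, c]
min_renditions: 15
```

## Conventions

Times are seconds, sample indices 0-based, intervals half-open
`[onset, offset)`. Amplitudes are arbitrary linear units. Annotation CSVs
use the schema `bout_id,rendition,label,onset_s,offset_s,condition`.
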