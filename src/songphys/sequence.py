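"""Syllable-sequence statistics.

Covers repeat collapsing (runs of identical syllables become a single song
element), branch-point transition tables, the generalized likelihood-ratio
test for homogeneity of transition probabilities between two conditions,
transition-change magnitude, transition entropy, repeat-run statistics, and
Pearson correlation.

A gap longer than ``max_gap`` (200 ms by default) breaks both repeat runs
and transitions: no transition is counted across it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from songphys.audio import SyllableEvent
from songphys.errors import DataError, ParameterError

__all__ = [
    "Element",
    "ElementSequence",
    "TransitionCounts",
    "RunLengths",
    "GLRResult",
    "ChangeMagnitude",
    "RepeatStats",
    "collapse_and_count",
    "classify_roles",
    "tally_transitions",
    "build_transition_counts",
    "transition_probabilities",
    "glr_homogeneity_test",
    "transition_change_magnitude",
    "transition_entropy",
    "repeat_statistics",
    "run_length_distribution",
    "pearson_correlation",
]


@dataclass(frozen=True)
class Element:
    """One song element: a syllable or a collapsed run of repeats."""

    label: str
    run_length: int
    gap_before: float = float("nan")

    def __post_init__(self) -> None:
        if self.run_length < 1:
            raise ParameterError("run_length must be >= 1")


@dataclass(frozen=True)
class ElementSequence:
    """Element sequences for one bout, split into segments at long gaps.

    Transitions are only defined within a segment; no two consecutive
    elements within a segment share a label.
    """

    segments: tuple[tuple[Element, ...], ...]

    def __post_init__(self) -> None:
        for seg in self.segments:
            for a, b in zip(seg[:-1], seg[1:]):
                if a.label == b.label:
                    raise ParameterError(
                        "consecutive identical elements within a segment"
                    )

    @property
    def elements(self) -> tuple[Element, ...]:
        return tuple(e for seg in self.segments for e in seg)


@dataclass(frozen=True)
class TransitionCounts:
    """Two-condition outcome counts at one branch point.

    Outcomes are in canonical order: descending baseline probability, ties
    broken by label. Outcome sets are unioned across conditions with zero
    fill.
    """

    branch: str
    outcomes: tuple[str, ...]
    counts_base: tuple[int, ...]
    counts_treat: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.outcomes) == len(self.counts_base) == len(self.counts_treat)
        ):
            raise ParameterError("outcomes and count vectors must align")
        if len(self.outcomes) < 2:
            raise ParameterError("a branch point needs at least 2 outcomes")
        if any(c < 0 for c in self.counts_base + self.counts_treat):
            raise ParameterError("counts must be nonnegative")


@dataclass(frozen=True)
class RunLengths:
    """Repeat-run-length samples for one syllable in two conditions."""

    label: str
    base: tuple[int, ...]
    treat: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.base + self.treat):
            raise ParameterError("run lengths must be >= 1")


class GLRResult(NamedTuple):
    statistic: float
    df: int
    p: float


class ChangeMagnitude(NamedTuple):
    summed: float  # sum of |delta p| over the first n-1 outcomes
    tv: float  # total-variation distance, ordering-invariant


@dataclass(frozen=True)
class RepeatStats:
    label: str
    mean_base: float
    mean_treat: float
    norm_count: float
    cv_base: float
    p: float


def collapse_and_count(
    bouts: Iterable[Sequence[SyllableEvent]], max_gap: float = 0.200
) -> list[ElementSequence]:
    """Collapse repeat runs and split sequences at long gaps.

    Consecutive identical labels separated by gaps <= ``max_gap`` merge
    into one element whose run length is the occurrence count. A gap
    longer than ``max_gap`` starts a new segment, terminating both the
    current run and any transition.
    """
    out: list[ElementSequence] = []
    for bout in bouts:
        segments: list[list[Element]] = [[]]
        prev: SyllableEvent | None = None
        for ev in bout:
            gap = float("nan") if prev is None else ev.onset - prev.offset
            if prev is not None and gap > max_gap:
                segments.append([])
                gap = float("nan")
            seg = segments[-1]
            if seg and seg[-1].label == ev.label:
                last = seg[-1]
                seg[-1] = Element(last.label, last.run_length + 1, last.gap_before)
            else:
                seg.append(Element(ev.label, 1, gap))
            prev = ev
        out.append(
            ElementSequence(tuple(tuple(seg) for seg in segments if seg))
        )
    return out


def classify_roles(
    sequences: Iterable[ElementSequence],
) -> tuple[set[str], set[str]]:
    """Identify branch-point and repeat-type labels.

    A label is repeat-type if any observed run reaches length >= 4 (runs of
    at most 3 are treated as branch-point material); it is a branch point
    if it has >= 2 distinct successor elements. A label can be both.
    """
    sequences = list(sequences)
    if not sequences:
        raise DataError("need at least one bout")
    successors: dict[str, set[str]] = {}
    max_run: dict[str, int] = {}
    for seq in sequences:
        for seg in seq.segments:
            for el in seg:
                max_run[el.label] = max(max_run.get(el.label, 0), el.run_length)
            for a, b in zip(seg[:-1], seg[1:]):
                successors.setdefault(a.label, set()).add(b.label)
    branch = {lab for lab, succ in successors.items() if len(succ) >= 2}
    repeat = {lab for lab, run in max_run.items() if run >= 4}
    return branch, repeat


def tally_transitions(
    sequences: Iterable[ElementSequence],
) -> dict[tuple[str, str], int]:
    """Element-level transition counts within segments."""
    counts: dict[tuple[str, str], int] = {}
    for seq in sequences:
        for seg in seq.segments:
            for a, b in zip(seg[:-1], seg[1:]):
                key = (a.label, b.label)
                counts[key] = counts.get(key, 0) + 1
    return counts


def build_transition_counts(
    branch: str,
    tally_base: dict[tuple[str, str], int],
    tally_treat: dict[tuple[str, str], int],
) -> TransitionCounts:
    """Assemble a two-condition table for one branch in canonical order."""
    outs = sorted(
        {b for (a, b) in tally_base if a == branch}
        | {b for (a, b) in tally_treat if a == branch}
    )
    if len(outs) < 2:
        raise DataError(f"label {branch!r} has fewer than 2 observed outcomes")
    base = np.array([tally_base.get((branch, o), 0) for o in outs], dtype=float)
    if base.sum() < 1:
        raise DataError(f"no baseline transitions observed for {branch!r}")
    p_base = base / base.sum()
    order = sorted(range(len(outs)), key=lambda i: (-p_base[i], outs[i]))
    return TransitionCounts(
        branch=branch,
        outcomes=tuple(outs[i] for i in order),
        counts_base=tuple(int(base[i]) for i in order),
        counts_treat=tuple(tally_treat.get((branch, outs[i]), 0) for i in order),
    )


def transition_probabilities(tc: TransitionCounts, condition: str) -> np.ndarray:
    """Maximum-likelihood outcome probabilities for one condition."""
    if condition == "base":
        counts = np.asarray(tc.counts_base, dtype=float)
    elif condition == "treat":
        counts = np.asarray(tc.counts_treat, dtype=float)
    else:
        raise ParameterError("condition must be 'base' or 'treat'")
    total = counts.sum()
    if total < 1:
        raise DataError(f"no transitions observed for condition {condition!r}")
    return counts / total


def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    # terms with zero counts contribute 0 (0 * log 0 := 0)
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(probs[mask])))


def glr_homogeneity_test(
    tc: TransitionCounts, n_monte_carlo: int | None = None, seed: int = 0
) -> GLRResult:
    """Generalized likelihood-ratio test of equal transition probabilities.

    The statistic is ``-2 (logL_sub - logL_full)`` where the full model
    fits one multinomial per condition and the sub model fits a single
    pooled multinomial. The p-value is the chi-squared upper tail with
    ``n - 1`` degrees of freedom; pass ``n_monte_carlo`` for an exact
    permutation-free parametric-bootstrap p on small tables.
    """
    c = np.asarray(tc.counts_base, dtype=float)
    d = np.asarray(tc.counts_treat, dtype=float)
    if c.sum() < 1 or d.sum() < 1:
        raise DataError("both condition totals must be >= 1")
    stat = _glr_statistic(c, d)
    df = len(tc.outcomes) - 1
    p = float(stats.chi2.sf(stat, df))
    if n_monte_carlo:
        rng = np.random.default_rng(seed)
        pooled = (c + d) / (c.sum() + d.sum())
        reps_c = rng.multinomial(int(c.sum()), pooled, size=n_monte_carlo)
        reps_d = rng.multinomial(int(d.sum()), pooled, size=n_monte_carlo)
        null = np.array(
            [_glr_statistic(a.astype(float), b.astype(float))
             for a, b in zip(reps_c, reps_d)]
        )
        p = float((1 + np.sum(null >= stat - 1e-12)) / (1 + n_monte_carlo))
    return GLRResult(statistic=stat, df=df, p=p)


def _glr_statistic(c: np.ndarray, d: np.ndarray) -> float:
    p_c = c / c.sum()
    p_d = d / d.sum()
    pooled = (c + d) / (c.sum() + d.sum())
    log_full = _multinomial_loglik(c, p_c) + _multinomial_loglik(d, p_d)
    log_sub = _multinomial_loglik(c, pooled) + _multinomial_loglik(d, pooled)
    return max(0.0, -2.0 * (log_sub - log_full))


def transition_change_magnitude(p_base, p_treat) -> ChangeMagnitude:
    """Summed |change| over the first n-1 outcomes, plus total variation.

    Expects probability vectors in canonical (descending baseline) order.
    The total-variation distance ``0.5 * sum |delta|`` is reported as an
    ordering-invariant companion; the two coincide for n = 2.
    """
    p = np.asarray(p_base, dtype=float)
    q = np.asarray(p_treat, dtype=float)
    if p.shape != q.shape:
        raise ParameterError("probability vectors must have equal length")
    delta = np.abs(q - p)
    return ChangeMagnitude(
        summed=float(delta[:-1].sum()), tv=float(0.5 * delta.sum())
    )


def transition_entropy(p) -> float:
    """Shannon entropy in bits, with 0 * log 0 := 0."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or abs(p.sum() - 1.0) > 1e-9):
        raise ParameterError("probabilities must be nonnegative and sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def repeat_statistics(rl: RunLengths) -> RepeatStats:
    """Per-condition mean run length, normalized repeat count, pooled
    baseline c.v., and a rank-sum p-value for the condition difference."""
    base = np.asarray(rl.base, dtype=float)
    treat = np.asarray(rl.treat, dtype=float)
    if base.size == 0 or treat.size == 0:
        raise DataError("each condition needs at least one run")
    mean_base = float(base.mean())
    mean_treat = float(treat.mean())
    cv_base = float(base.std(ddof=1) / mean_base) if base.size > 1 else 0.0
    if np.array_equal(np.sort(base), np.sort(treat)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(treat, base, alternative="two-sided").pvalue)
    return RepeatStats(
        label=rl.label,
        mean_base=mean_base,
        mean_treat=mean_treat,
        norm_count=mean_treat / mean_base,
        cv_base=cv_base,
        p=p,
    )


def run_length_distribution(runs: Sequence[int]) -> np.ndarray:
    """Normalized run-length histogram p_i = fraction of runs of length i,
    used as the outcome distribution when computing entropy for repeats."""
    runs = np.asarray(runs, dtype=int)
    if runs.size == 0:
        raise DataError("no runs provided")
    counts = np.bincount(runs)[1:]
    return counts / counts.sum()


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-based p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need equal-length inputs with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DataError("zero variance in an input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
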