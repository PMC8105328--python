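"""Ordinal symbolization and permutation entropy of eye-position series.

A delay vector of dimension ``d`` (lag 1) is mapped to the permutation
``[j_1 ... j_d]`` of ``1..d`` that arranges its values into increasing order,
with ties broken by original position (earlier index ranks first).  The
permutation entropy is the Shannon entropy of the empirical distribution of
these patterns,

    H_p = - sum_j P_j ln P_j   (nats),

normalized as h_p = H_p / ln(d!) so that 0 <= h_p <= 1.  The sliding-window
variant computes h_p on overlapping windows of fixed duration T_w after a
moving-average detrend of the whole series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as _stats

__all__ = [
    "PatternDistribution",
    "EntropyResult",
    "EntropyWindowSeries",
    "EntropyComparison",
    "detrend_moving_average",
    "ordinal_patterns",
    "ordinal_distribution",
    "permutation_entropy",
    "sliding_entropy",
    "compare_entropies",
    "min_window_duration",
]


def detrend_moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Subtract a centred moving average (baseline-drift removal).

    ``window`` must be odd, >= 3 and <= the series length.  Edges use
    shrinking (truncated) windows so the output has the input's length.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if window < 3 or window % 2 == 0 or window > n:
        raise ValueError(
            f"window must be odd, >= 3 and <= series length; got {window} for n={n}"
        )
    h = window // 2
    c = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    lo = np.maximum(0, i - h)
    hi = np.minimum(n, i + h + 1)
    means = (c[hi] - c[lo]) / (hi - lo)
    return x - means


@dataclass
class PatternDistribution:
    """Empirical distribution of ordinal patterns (1-based permutations)."""

    patterns: np.ndarray  # (K, d) int array, each row a permutation of 1..d
    probabilities: np.ndarray  # (K,) summing to 1
    d: int
    total_vectors: int

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        k = len(self.probabilities)
        if k == 0:
            raise ValueError("empty distribution")
        if k > math.factorial(self.d):
            raise ValueError("more patterns than d! permutations")
        if np.any(self.probabilities <= 0):
            raise ValueError("probabilities must be positive")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass(frozen=True)
class EntropyResult:
    H_p: float  # nats
    h_p: float  # H_p / ln(d!) in [0, 1]
    d: int


@dataclass
class EntropyWindowSeries:
    """Per-window normalized permutation entropy of one series."""

    window_starts: np.ndarray  # seconds
    h_p_values: np.ndarray
    T_w: float  # seconds
    d: int
    subject_id: str = ""

    def __len__(self) -> int:
        return len(self.h_p_values)


@dataclass
class EntropyComparison:
    labels: list[str]
    medians: dict[str, float]
    mads: dict[str, float]
    raw_p: dict[tuple[str, str], float]
    adjusted_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    ranking: list[str]  # by increasing median h_p
    alpha: float
    n_pairs: int


def ordinal_patterns(series: np.ndarray, d: int) -> np.ndarray:
    """Ordinal pattern of every length-``d`` delay vector (lag 1).

    Returns an ``(N - d + 1, d)`` int array of 1-based permutations; row i is
    the ``[j_1 ... j_d]`` such that ``x[i + j_1 - 1] <= ... <= x[i + j_d - 1]``,
    ties broken by earlier index.
    """
    x = np.asarray(series, dtype=float)
    if d < 2:
        raise ValueError("d must be >= 2")
    if x.size < d:
        raise ValueError(f"series length {x.size} is shorter than d={d}")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    windows = sliding_window_view(x, d)
    return np.argsort(windows, axis=1, kind="stable") + 1


def _pattern_codes(patterns: np.ndarray, d: int) -> np.ndarray:
    # injective encoding of permutation rows as base-d integers
    weights = d ** np.arange(d, dtype=np.int64)
    return (patterns.astype(np.int64) - 1) @ weights


def ordinal_distribution(series: np.ndarray, d: int) -> PatternDistribution:
    """Empirical ordinal-pattern distribution of a series at dimension d."""
    pats = ordinal_patterns(series, d)
    codes = _pattern_codes(pats, d)
    _, first, counts = np.unique(codes, return_index=True, return_counts=True)
    return PatternDistribution(
        patterns=pats[first],
        probabilities=counts / counts.sum(),
        d=d,
        total_vectors=len(codes),
    )


def permutation_entropy(distribution: PatternDistribution) -> EntropyResult:
    """Shannon entropy of an ordinal-pattern distribution (natural log)."""
    p = distribution.probabilities
    H = float(-np.sum(p * np.log(p))) if len(p) > 1 else 0.0
    return EntropyResult(
        H_p=H, h_p=H / math.log(math.factorial(distribution.d)), d=distribution.d
    )


def min_window_duration(d: int, rate: float) -> float:
    """Shortest window (s) whose sample count equals d! at the given rate."""
    return math.factorial(d) / rate


def _entropy_from_counts(counts: np.ndarray) -> float:
    c = counts[counts > 0]
    if c.size <= 1:
        return 0.0
    n = c.sum()
    return float(math.log(n) - np.sum(c * np.log(c)) / n)


def sliding_entropy(
    series: np.ndarray,
    rate: float,
    d: int = 7,
    T_w: float | None = None,
    hop_s: float = 0.5,
    detrend_window_s: float | None = 4.0,
    subject_id: str = "",
) -> EntropyWindowSeries:
    """Normalized permutation entropy h_p over overlapping windows.

    ``T_w`` defaults to ``d! / rate`` seconds, the shortest window in which
    every ordinal pattern could potentially be observed (25.2 s for d = 7 at
    200 Hz).  The whole series is detrended once (moving average,
    ``detrend_window_s``) before windowing.
    """
    x = np.asarray(series, dtype=float)
    if T_w is None:
        T_w = min_window_duration(d, rate)
    win = int(round(T_w * rate))
    if win < math.factorial(d):
        warnings.warn(
            f"window of {win} samples cannot realise all {math.factorial(d)} "
            f"patterns at d={d}",
            stacklevel=2,
        )
    if x.size < win:
        raise ValueError(f"series of {x.size} samples is shorter than one window ({win})")
    if detrend_window_s is not None:
        w = min(int(round(detrend_window_s * rate)) | 1, (x.size - 1) | 1)
        x = detrend_moving_average(x, w)
    hop = max(1, int(round(hop_s * rate)))

    codes = _pattern_codes(ordinal_patterns(x, d), d)
    # dense re-labelling so per-window tallies are cheap bincounts
    _, dense = np.unique(codes, return_inverse=True)
    n_labels = int(dense.max()) + 1
    log_dfact = math.log(math.factorial(d))

    starts = np.arange(0, x.size - win + 1, hop)
    h_vals = np.empty(len(starts))
    per_win = win - d + 1
    for k, s in enumerate(starts):
        counts = np.bincount(dense[s : s + per_win], minlength=n_labels)
        h_vals[k] = _entropy_from_counts(counts) / log_dfact
    return EntropyWindowSeries(
        window_starts=starts / rate,
        h_p_values=h_vals,
        T_w=win / rate,
        d=d,
        subject_id=subject_id,
    )


def compare_entropies(
    series_list: list[EntropyWindowSeries], alpha: float = 0.01
) -> EntropyComparison:
    """Pairwise two-sided rank-sum tests on window h_p values.

    Wilcoxon-Mann-Whitney with normal approximation and tie correction;
    Bonferroni adjustment over the number of pairs.  Series are ranked by
    increasing median h_p (increasing waveform complexity).
    """
    if len(series_list) < 2:
        raise ValueError("need at least two entropy series to compare")
    for s in series_list:
        if len(s) < 5:
            raise ValueError(f"series {s.subject_id!r} has fewer than 5 windows")
    labels = [
        s.subject_id if s.subject_id else f"series{i}"
        for i, s in enumerate(series_list)
    ]
    if len(set(labels)) != len(labels):
        raise ValueError("series labels must be unique")
    values = {lab: np.asarray(s.h_p_values) for lab, s in zip(labels, series_list)}
    medians = {lab: float(np.median(v)) for lab, v in values.items()}
    mads = {
        lab: float(_stats.median_abs_deviation(v)) for lab, v in values.items()
    }
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    raw: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        pooled = np.concatenate([values[a], values[b]])
        if np.all(pooled == pooled[0]):
            raw[(a, b)] = 1.0
            continue
        res = _stats.mannwhitneyu(
            values[a], values[b], alternative="two-sided", method="asymptotic"
        )
        raw[(a, b)] = float(res.pvalue)
    m = len(pairs)
    adjusted = {k: min(1.0, v * m) for k, v in raw.items()}
    significant = {k: bool(v < alpha) for k, v in adjusted.items()}
    ranking = sorted(labels, key=lambda lab: medians[lab])
    return EntropyComparison(
        labels=labels,
        medians=medians,
        mads=mads,
        raw_p=raw,
        adjusted_p=adjusted,
        significant=significant,
        ranking=ranking,
        alpha=alpha,
        n_pairs=m,
    )
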