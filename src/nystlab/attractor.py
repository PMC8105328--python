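"""Delay embedding, principal-component projection and attractor class.

A window of length d (the embedding dimension, default 7, lag 1 sample) is
slid across the series to form delay vectors; these are projected onto
their first three principal components for visualisation.  The attractor
class (fixed point / limit cycle / torus / higher-dimensional) is decided by
an explicit spectral heuristic: harmonically related peaks concentrating the
power indicate a limit cycle, two incommensurate fundamentals a torus, and
broadband or unresolved structure a higher-dimensional attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as _signal

from .spectral import amplitude_spectrum
from .upo import UPOResult

__all__ = [
    "DelayEmbedding",
    "ProjectedTrajectory",
    "AttractorClass",
    "delay_embed",
    "project_principal",
    "classify_attractor",
]

DEFAULT_DIMENSION = 7


@dataclass
class DelayEmbedding:
    """(N - (d-1)*lag) x d matrix of delay vectors."""

    vectors: np.ndarray
    d: int
    lag: int = 1


@dataclass
class ProjectedTrajectory:
    coordinates: np.ndarray  # rows x n_components scores
    explained_variance: np.ndarray  # fractions of the total variance
    component_vectors: np.ndarray  # n_components x d, orthonormal rows


@dataclass
class AttractorClass:
    label: str  # fixed_point | limit_cycle | torus | higher_dimensional
    evidence: dict = field(default_factory=dict)


def delay_embed(series: np.ndarray, d: int = DEFAULT_DIMENSION, lag: int = 1) -> DelayEmbedding:
    """Delay vectors [x(i), x(i+lag), ..., x(i+(d-1)lag)] for every i."""
    x = np.asarray(series, dtype=float)
    if d < 2 or lag < 1:
        raise ValueError("need d >= 2 and lag >= 1")
    span = (d - 1) * lag + 1
    if x.size < span:
        raise ValueError(f"series of {x.size} samples is too short for d={d}, lag={lag}")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    vectors = sliding_window_view(x, span)[:, ::lag]
    return DelayEmbedding(vectors=np.ascontiguousarray(vectors), d=d, lag=lag)


def project_principal(
    embedding: DelayEmbedding, n_components: int = 3
) -> ProjectedTrajectory:
    """Project delay vectors onto their leading principal components.

    Columns are mean-centred; components are covariance eigenvectors by
    decreasing eigenvalue; explained variances are eigenvalue fractions of
    the total over all d dimensions.
    """
    X = embedding.vectors
    if n_components < 1 or n_components > embedding.d:
        raise ValueError("n_components must be in 1..d")
    if X.shape[0] < embedding.d:
        raise ValueError("need at least d delay vectors")
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-12 * X.shape[0]:
        raise ValueError("rank-0 data: constant series has no principal axes")
    components = Vt[:n_components]
    return ProjectedTrajectory(
        coordinates=Xc @ components.T,
        explained_variance=(s[:n_components] ** 2) / total,
        component_vectors=components,
    )


def _is_harmonic_set(
    peaks: np.ndarray, f0: float, rel_tol: float, abs_tol: float
) -> bool:
    """True when every peak sits within tolerance of an integer multiple of f0."""
    tol = max(rel_tol * f0, abs_tol)
    mult = np.round(peaks / f0)
    return bool(np.all(mult >= 1) and np.all(np.abs(peaks - mult * f0) <= tol))


def _incommensurate(f1: float, f2: float, abs_tol: float, max_q: int = 4) -> bool:
    """True when f2/f1 is further than abs_tol from every rational p/q, q <= max_q."""
    for q in range(1, max_q + 1):
        for p in range(1, int(np.ceil(f2 / f1 * q)) + 2):
            if abs(f2 - (p / q) * f1) <= abs_tol:
                return False
    return True


def classify_attractor(
    segment: np.ndarray,
    rate: float,
    upo: UPOResult | None = None,
    quiescence_sd: float = 0.05,
    peak_height: float = 0.08,
    harmonic_tol: float = 0.05,
    concentration_threshold: float = 0.85,
    min_freq: float | None = None,
) -> AttractorClass:
    """Heuristic attractor classification from a segment's amplitude spectrum.

    Near-zero oscillation (SD below ``quiescence_sd`` degrees) is a fixed
    point.  Otherwise prominent spectral peaks (relative amplitude >=
    ``peak_height``) are located; if the power is concentrated at the peaks
    and they form a single harmonic series the segment is a limit cycle,
    if they reduce to two incommensurate fundamentals it is a torus, and
    everything else (broadband / unresolvable structure) is
    higher-dimensional.  Deterministic given the segment.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 16:
        raise ValueError("segment too short to classify")
    if float(np.std(x)) < quiescence_sd:
        return AttractorClass(label="fixed_point", evidence={"sd": float(np.std(x))})

    pad = max(1, x.size // 4)
    spec = amplitude_spectrum(x, rate, pad=pad)
    res = spec.resolution
    if min_freq is None:
        min_freq = 3 * res
    freqs, rel = spec.frequencies, spec.relative_amplitudes
    valid = freqs >= min_freq
    peak_idx, _ = _signal.find_peaks(rel, height=peak_height, prominence=peak_height / 2)
    peak_idx = np.array([i for i in peak_idx if valid[i]], dtype=int)
    evidence: dict = {"resolution": res, "segment_sd": float(np.std(x))}
    if peak_idx.size == 0:
        return AttractorClass(label="higher_dimensional", evidence=evidence)
    peak_freqs = freqs[peak_idx]
    peak_amps = rel[peak_idx]
    evidence["peaks"] = [(float(f), float(a)) for f, a in zip(peak_freqs, peak_amps)]

    # fraction of oscillation power captured within the mainlobes of the peaks
    power = spec.magnitudes**2
    total = float(power[valid].sum())
    half_width = 4  # bins; Bartlett mainlobe at the default quarter-length pad
    near = np.zeros_like(power, dtype=bool)
    for i in peak_idx:
        near[max(0, i - half_width) : i + half_width + 1] = True
    concentration = float(power[near & valid].sum() / total) if total > 0 else 0.0
    evidence["concentration"] = concentration

    if concentration < concentration_threshold:
        return AttractorClass(label="higher_dimensional", evidence=evidence)

    # try each peak as the fundamental of a single harmonic series
    for f0 in np.sort(peak_freqs):
        if _is_harmonic_set(peak_freqs, float(f0), harmonic_tol, 2 * res):
            evidence["fundamental"] = float(f0)
            return AttractorClass(label="limit_cycle", evidence=evidence)

    # two strongest peaks as candidate incommensurate fundamentals
    order = np.argsort(-peak_amps)
    f1, f2 = sorted(float(peak_freqs[i]) for i in order[:2])
    evidence["fundamentals"] = (f1, f2)
    if f1 > 0 and _incommensurate(f1, f2, abs_tol=2 * res):
        # remaining peaks must be integer combinations m*f1 + n*f2
        others = np.array(
            [f for f in peak_freqs if abs(f - f1) > res and abs(f - f2) > res]
        )
        combo_ok = True
        for f in others:
            hit = False
            for m in range(0, 5):
                for n in range(-4, 5):
                    cand = m * f1 + n * f2
                    if cand > 0 and abs(f - cand) <= 2 * res:
                        hit = True
            if not hit:
                combo_ok = False
        if combo_ok:
            return AttractorClass(label="torus", evidence=evidence)
    return AttractorClass(label="higher_dimensional", evidence=evidence)
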