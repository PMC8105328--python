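"""Standard clinical assessment of an eye-movement recording.

Position statistics per channel, per-cycle amplitude/frequency of the
oscillating channel, oscillation intensity (amplitude x frequency), a
fixation-stability flag, and a velocity-threshold detector for small
saccadic intrusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .entropy import detrend_moving_average
from .io import EyeMovementRecording, EyeTrace

__all__ = [
    "PositionSummary",
    "CycleMetrics",
    "ClinicalSummary",
    "IntrusionEvent",
    "position_summary",
    "cycle_metrics",
    "clinical_summary",
    "detect_saccadic_intrusions",
    "ARCMIN_PER_DEGREE",
]

ARCMIN_PER_DEGREE = 60.0

#: Default fixation-stability bounds (arcmin on the mean and on the SD).
STABILITY_MEAN_ARCMIN = 10.0
STABILITY_SD_ARCMIN = 10.0


@dataclass(frozen=True)
class PositionSummary:
    mean: float  # degrees
    sd: float  # degrees


@dataclass(frozen=True)
class CycleMetrics:
    """Amplitude/period of one oscillation cycle (maximum k to maximum k+1)."""

    cycle_index: int
    amplitude: float  # degrees, peak-to-peak within the cycle
    period: float  # seconds, spacing of successive maxima

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be > 0")

    @property
    def frequency(self) -> float:
        return 1.0 / self.period


@dataclass
class ClinicalSummary:
    channel_stats: dict[str, PositionSummary]
    fixation_stable: dict[str, bool]
    oscillating_channel: str
    mean_amplitude: float  # degrees
    mean_frequency: float  # Hz
    n_cycles: int

    @property
    def intensity(self) -> float:
        """Oscillation intensity in degrees*Hz (amplitude x frequency)."""
        return self.mean_amplitude * self.mean_frequency


@dataclass(frozen=True)
class IntrusionEvent:
    onset: float  # seconds
    amplitude: float  # degrees, absolute step size
    direction: int  # +1 / -1
    paired: bool = False  # part of a back-to-back pair

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def position_summary(trace: EyeTrace, ddof: int = 1) -> PositionSummary:
    """Mean and SD of a position trace in degrees (sample SD by default)."""
    x = trace.samples
    if not np.isfinite(x).all():
        raise ValueError("trace contains non-finite samples; preprocess first")
    sd = float(np.std(x, ddof=ddof)) if x.size > ddof else 0.0
    return PositionSummary(mean=float(np.mean(x)), sd=sd)


def _default_prominence(x: np.ndarray) -> float:
    iqr = float(_stats.iqr(x))
    if iqr <= 0:
        iqr = float(np.ptp(x))
    return 0.25 * iqr


def cycle_metrics(
    trace: EyeTrace,
    prominence: float | None = None,
    detrend_window_s: float | None = None,
) -> list[CycleMetrics]:
    """Per-cycle amplitude and period from prominence-selected extrema.

    A cycle spans successive maxima; its amplitude is max - min of the
    samples in between, its period the maxima spacing.  ``prominence``
    defaults to 25% of the interquartile range of the (detrended) trace.
    """
    x = trace.samples
    if detrend_window_s is not None:
        w = int(round(detrend_window_s * trace.rate)) | 1
        x = detrend_moving_average(x, w)
    if prominence is None:
        prominence = _default_prominence(x)
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    maxima, _ = _signal.find_peaks(x, prominence=prominence)
    if len(maxima) < 2:
        raise ValueError("fewer than two maxima found; cannot form cycles")
    cycles = []
    for k, (a, b) in enumerate(zip(maxima[:-1], maxima[1:])):
        seg = x[a : b + 1]
        cycles.append(
            CycleMetrics(
                cycle_index=k,
                amplitude=float(seg.max() - seg.min()),
                period=float((b - a) / trace.rate),
            )
        )
    return cycles


def clinical_summary(
    recording: EyeMovementRecording,
    oscillating_channel: str,
    prominence: float | None = None,
    detrend_window_s: float | None = 4.0,
    stability_mean_arcmin: float = STABILITY_MEAN_ARCMIN,
    stability_sd_arcmin: float = STABILITY_SD_ARCMIN,
) -> ClinicalSummary:
    """Aggregate position statistics and cycle metrics for one recording.

    A channel is flagged fixation-stable when |mean| <= 10 arcmin and
    SD <= the configured bound (default also 10 arcmin).
    """
    stats = {t.channel: position_summary(t) for t in recording.traces}
    mean_limit = stability_mean_arcmin / ARCMIN_PER_DEGREE
    sd_limit = stability_sd_arcmin / ARCMIN_PER_DEGREE
    stable = {
        ch: bool(abs(s.mean) <= mean_limit and s.sd <= sd_limit)
        for ch, s in stats.items()
    }
    cycles = cycle_metrics(
        recording.trace(oscillating_channel),
        prominence=prominence,
        detrend_window_s=detrend_window_s,
    )
    return ClinicalSummary(
        channel_stats=stats,
        fixation_stable=stable,
        oscillating_channel=oscillating_channel,
        mean_amplitude=float(np.mean([c.amplitude for c in cycles])),
        mean_frequency=float(np.mean([c.frequency for c in cycles])),
        n_cycles=len(cycles),
    )


def detect_saccadic_intrusions(
    trace: EyeTrace,
    velocity_threshold: float = 20.0,
    amplitude_band: tuple[float, float] = (0.3, 1.0),
    smooth_ms: float = 10.0,
    pair_gap_s: float = 0.3,
) -> list[IntrusionEvent]:
    """Detect small step-like intrusions by a velocity-threshold criterion.

    Events are contiguous runs where the smoothed velocity exceeds
    ``velocity_threshold`` (deg/s) whose net position step falls inside
    ``amplitude_band`` (degrees).  Back-to-back events of opposite
    direction within ``pair_gap_s`` are flagged as paired.
    """
    if velocity_threshold <= 0:
        raise ValueError("velocity_threshold must be positive")
    lo, hi = amplitude_band
    if lo <= 0 or hi <= lo:
        raise ValueError("amplitude_band must satisfy 0 < lo < hi")
    x = trace.samples
    rate = trace.rate
    if x.size < 3:
        return []
    v = np.gradient(x) * rate
    w = max(1, int(round(smooth_ms / 1000.0 * rate)))
    if w > 1:
        v = np.convolve(v, np.ones(w) / w, mode="same")
    above = np.abs(v) >= velocity_threshold
    events: list[tuple[float, float, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    pad = w + 2  # cover ramp tails blurred by the velocity smoothing
    for start, stop in zip(idx[::2], idx[1::2]):
        a = max(0, int(start) - pad)
        b = min(len(x) - 1, int(stop) + pad - 1)
        step = float(x[b] - x[a])
        if lo <= abs(step) <= hi:
            events.append((a / rate, abs(step), int(np.sign(step))))
    out: list[IntrusionEvent] = []
    paired = [False] * len(events)
    for i in range(len(events) - 1):
        if (
            events[i + 1][0] - events[i][0] <= pair_gap_s
            and events[i + 1][2] == -events[i][2]
        ):
            paired[i] = paired[i + 1] = True
    for (onset, amp, sign), p in zip(events, paired):
        out.append(IntrusionEvent(onset=onset, amplitude=amp, direction=sign, paired=p))
    return out
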