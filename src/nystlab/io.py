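"""Recording data model and delimited-text I/O for eye-position traces.

Recordings are stored as delimited text (CSV/TSV) with a header row.  The
canonical columns are ``time_s`` plus any subset of ``r_h_deg``, ``r_v_deg``,
``l_h_deg`` and ``l_v_deg``; positions are always in degrees.  Time is
represented implicitly inside the package: sample ``i`` of a trace occurs at
``i / rate`` seconds (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "CHANNELS",
    "SamplingSpec",
    "EyeTrace",
    "EyeMovementRecording",
    "infer_rate",
    "load_recording",
    "write_recording",
    "preprocess_trace",
]

#: Recognised channel labels: right/left eye, horizontal/vertical plane.
CHANNELS = ("R_H", "R_V", "L_H", "L_V")

#: Canonical file column for each channel.
COLUMN_FOR_CHANNEL = {
    "R_H": "r_h_deg",
    "R_V": "r_v_deg",
    "L_H": "l_h_deg",
    "L_V": "l_v_deg",
}
CHANNEL_FOR_COLUMN = {v: k for k, v in COLUMN_FOR_CHANNEL.items()}

_RECOGNISED_UNITS = ("deg", "degrees")


@dataclass(frozen=True)
class SamplingSpec:
    """Uniform sampling metadata for a trace."""

    rate: float
    units: str = "deg"

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate!r}")
        if self.units not in _RECOGNISED_UNITS:
            raise ValueError(f"unrecognised units {self.units!r}")


@dataclass
class EyeTrace:
    """One channel of eye position in degrees with sampling metadata."""

    channel: str
    samples: np.ndarray
    sampling: SamplingSpec

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def rate(self) -> float:
        return self.sampling.rate

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Duration in seconds (= n_samples / rate)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (sample i at i / rate)."""
        return np.arange(self.n_samples) / self.rate

    def with_samples(self, samples: np.ndarray, rate: float | None = None) -> "EyeTrace":
        sampling = self.sampling if rate is None else replace(self.sampling, rate=rate)
        return EyeTrace(self.channel, np.asarray(samples, dtype=float), sampling)


@dataclass
class EyeMovementRecording:
    """A multi-channel recording from one subject.

    All traces share one :class:`SamplingSpec` and channel labels are unique.
    """

    subject_id: str
    traces: list[EyeTrace]
    notes: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.traces) <= 4:
            raise ValueError("a recording holds between 1 and 4 traces")
        labels = [t.channel for t in self.traces]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate channel labels: {labels}")
        specs = {t.sampling for t in self.traces}
        if len(specs) != 1:
            raise ValueError("all traces must share one sampling spec")

    @property
    def rate(self) -> float:
        return self.traces[0].rate

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(t.channel for t in self.traces)

    def trace(self, channel: str) -> EyeTrace:
        for t in self.traces:
            if t.channel == channel:
                return t
        raise KeyError(f"channel {channel!r} not present (have {self.channels})")


def infer_rate(time_s: np.ndarray, tol: float = 0.01) -> float:
    """Infer the sampling rate from a time column (seconds).

    The rate is ``1 / median(diff(time_s))``.  Raises if the column is not
    strictly increasing or if any spacing deviates from the median by more
    than ``tol`` (relative).  Near-integer rates are snapped to the integer so
    that a column generated as ``arange(n) / rate`` round-trips exactly.
    """
    t = np.asarray(time_s, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time stamps to infer a rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > tol * med:
        raise ValueError(
            "time column spacing varies by more than "
            f"{tol:.0%}; cannot infer a uniform sampling rate"
        )
    rate = 1.0 / med
    if abs(rate - round(rate)) < 1e-6 * rate:
        rate = float(round(rate))
    return rate


def _resolve_columns(
    columns: list[str], channel_map: dict[str, str] | None, time_column: str
) -> dict[str, str]:
    """Map channel label -> file column, validating against the header."""
    if channel_map is None:
        mapping = {
            ch: col for col, ch in CHANNEL_FOR_COLUMN.items() if col in columns
        }
    else:
        bad = {ch for ch in channel_map if ch not in CHANNELS}
        if bad:
            raise ValueError(f"unknown channels in mapping: {sorted(bad)}")
        missing = {col for col in channel_map.values() if col not in columns}
        if missing:
            raise ValueError(f"mapped columns not in file: {sorted(missing)}")
        mapping = dict(channel_map)
    if not mapping:
        raise ValueError(
            f"no position columns found; file has {columns}, "
            f"expected some of {sorted(CHANNEL_FOR_COLUMN)} or an explicit mapping"
        )
    return mapping


def load_recording(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
    rate: float | None = None,
    time_column: str = "time_s",
    subject_id: str | None = None,
) -> EyeMovementRecording:
    """Load a delimited-text recording.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    channel_map:
        Optional mapping from channel label (``R_H`` ...) to file column.
        Defaults to the canonical ``r_h_deg`` ... columns present in the file.
    rate:
        Sampling rate override (Hz).  If omitted it is inferred from the
        ``time_column`` (median spacing; spacing must be uniform to 1%).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    columns = list(frame.columns)
    mapping = _resolve_columns(columns, channel_map, time_column)

    if rate is None:
        if time_column not in columns:
            raise ValueError(
                f"no {time_column!r} column and no explicit rate given"
            )
        rate = infer_rate(frame[time_column].to_numpy())
    sampling = SamplingSpec(rate=float(rate))

    traces = [
        EyeTrace(ch, frame[col].to_numpy(dtype=float), sampling)
        for ch, col in sorted(mapping.items(), key=lambda kv: CHANNELS.index(kv[0]))
    ]
    return EyeMovementRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        traces=traces,
    )


def write_recording(recording: EyeMovementRecording, path: str | Path) -> Path:
    """Write a recording as CSV with a ``time_s`` column (full precision)."""
    path = Path(path)
    n = recording.traces[0].n_samples
    if any(t.n_samples != n for t in recording.traces):
        raise ValueError("all traces must have equal length to be written")
    data = {"time_s": np.arange(n) / recording.rate}
    for t in recording.traces:
        data[COLUMN_FOR_CHANNEL[t.channel]] = t.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def _gap_runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True as (start, stop) half-open index pairs."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], bad.astype(int), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append((int(start), int(stop)))
    return runs


def preprocess_trace(
    trace: EyeTrace,
    gap_policy: str = "linear-interpolate",
    target_rate: float | None = None,
    max_gap_s: float = 0.5,
) -> EyeTrace:
    """Fill gaps (blinks/dropouts encoded as NaN) and optionally resample.

    ``gap_policy`` is ``"linear-interpolate"`` (default; interior gaps are
    linearly interpolated, edge gaps held at the nearest finite value) or
    ``"drop-leading-trailing"`` (edge gaps trimmed; interior gaps are an
    error).  Gaps longer than ``max_gap_s`` raise.  If ``target_rate`` is
    given the trace is resampled with a polyphase anti-alias filter; the
    ratio ``target_rate / rate`` must be rational.
    """
    if gap_policy not in ("linear-interpolate", "drop-leading-trailing"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    x = np.asarray(trace.samples, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("trace is entirely non-finite")

    rate = trace.rate
    if not finite.all():
        max_gap = int(np.ceil(max_gap_s * rate))
        for start, stop in _gap_runs(~finite):
            if stop - start > max_gap:
                raise ValueError(
                    f"gap of {(stop - start) / rate:.3f} s exceeds the "
                    f"{max_gap_s} s maximum"
                )
        if gap_policy == "drop-leading-trailing":
            lo = int(np.argmax(finite))
            hi = int(len(x) - np.argmax(finite[::-1]))
            x = x[lo:hi]
            if not np.isfinite(x).all():
                raise ValueError(
                    "interior gap present; use gap_policy='linear-interpolate'"
                )
        else:
            idx = np.arange(len(x))
            x = x.copy()
            x[~finite] = np.interp(idx[~finite], idx[finite], x[finite])
    out = x

    if target_rate is not None:
        ratio = Fraction(target_rate / rate).limit_denominator(1000)
        if abs(float(ratio) * rate - target_rate) > 1e-9 * target_rate:
            raise ValueError(
                f"target rate {target_rate} is not a rational multiple of {rate}"
            )
        out = _signal.resample_poly(out, ratio.numerator, ratio.denominator)
        return trace.with_samples(out, rate=float(target_rate))

    if out is trace.samples or (out.shape == trace.samples.shape and finite.all()):
        # no gaps, no resampling: identity
        return trace.with_samples(trace.samples.copy())
    return trace.with_samples(out)
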