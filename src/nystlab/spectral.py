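"""Segmented Fourier amplitude spectra of eye-position traces.

Each segment is mean-removed, weighted by a symmetric triangular (Bartlett)
taper, zero-padded at both ends, and transformed; the one-sided magnitude
spectrum is reported with amplitudes normalized to a maximum of 1.  With the
default 4000-sample window and 1000-sample pads at 200 Hz the frequency
resolution is 200 / 6000 ~ 0.033 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EyeTrace

__all__ = [
    "AmplitudeSpectrum",
    "amplitude_spectrum",
    "successive_spectra",
    "mean_spectrum",
    "dominant_frequency",
    "DEFAULT_WINDOW_LEN",
    "DEFAULT_PAD",
]

DEFAULT_WINDOW_LEN = 4000
DEFAULT_PAD = 1000


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a tapered, padded segment."""

    frequencies: np.ndarray  # Hz, uniform from 0 to rate/2
    relative_amplitudes: np.ndarray  # max-normalized, >= 0
    magnitudes: np.ndarray  # unnormalized |FFT|
    resolution: float  # Hz = rate / padded_length
    segment_start: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.relative_amplitudes = np.asarray(self.relative_amplitudes, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.frequencies.shape != self.relative_amplitudes.shape:
            raise ValueError("frequency and amplitude grids differ in shape")


def amplitude_spectrum(
    segment: np.ndarray,
    rate: float,
    window_len: int | None = None,
    pad: int = DEFAULT_PAD,
    segment_start: float = 0.0,
) -> AmplitudeSpectrum:
    """Amplitude spectrum of one segment.

    ``window_len`` defaults to the segment length; a mismatched segment is an
    error.  The segment is mean-removed, multiplied by a triangular taper
    (1 at the centre, 0 at the ends), and padded by ``pad`` zeros at either
    end, giving resolution ``rate / (window_len + 2 * pad)``.
    """
    x = np.asarray(segment, dtype=float)
    if window_len is None:
        window_len = x.size
    if x.size != window_len:
        raise ValueError(
            f"segment of {x.size} samples does not match window_len={window_len}"
        )
    if not np.isfinite(x).all():
        raise ValueError("segment contains non-finite values")
    taper = np.bartlett(window_len)
    tapered = (x - x.mean()) * taper
    padded = np.concatenate([np.zeros(pad), tapered, np.zeros(pad)])
    mag = np.abs(np.fft.rfft(padded))
    freqs = np.fft.rfftfreq(padded.size, d=1.0 / rate)
    peak = mag.max()
    rel = mag / peak if peak > 0 else mag.copy()
    return AmplitudeSpectrum(
        frequencies=freqs,
        relative_amplitudes=rel,
        magnitudes=mag,
        resolution=rate / padded.size,
        segment_start=segment_start,
    )


def successive_spectra(
    trace: EyeTrace,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int | None = None,
    pad: int = DEFAULT_PAD,
) -> list[AmplitudeSpectrum]:
    """One spectrum per complete ``window_len`` segment (default: no overlap)."""
    if hop is None:
        hop = window_len
    if hop < 1:
        raise ValueError("hop must be >= 1")
    x = trace.samples
    if x.size < window_len:
        raise ValueError(
            f"trace of {x.size} samples is shorter than one {window_len}-sample window"
        )
    n_segments = (x.size - window_len) // hop + 1
    return [
        amplitude_spectrum(
            x[k * hop : k * hop + window_len],
            trace.rate,
            window_len=window_len,
            pad=pad,
            segment_start=k * hop / trace.rate,
        )
        for k in range(n_segments)
    ]


def mean_spectrum(spectra: list[AmplitudeSpectrum]) -> AmplitudeSpectrum:
    """Average the relative amplitudes of same-grid spectra (re-normalized)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != grid.shape or not np.allclose(s.frequencies, grid):
            raise ValueError("spectra are on different frequency grids")
    mean_rel = np.mean([s.relative_amplitudes for s in spectra], axis=0)
    mean_mag = np.mean([s.magnitudes for s in spectra], axis=0)
    peak = mean_rel.max()
    return AmplitudeSpectrum(
        frequencies=grid.copy(),
        relative_amplitudes=mean_rel / peak if peak > 0 else mean_rel,
        magnitudes=mean_mag,
        resolution=spectra[0].resolution,
        segment_start=spectra[0].segment_start,
    )


def dominant_frequency(
    spectrum: AmplitudeSpectrum, min_freq: float | None = None
) -> float:
    """Frequency of the largest amplitude at or above ``min_freq``.

    ``min_freq`` defaults to one bin, excluding the 0 Hz/drift bin.  Ties
    break toward the lower frequency.
    """
    if spectrum.frequencies.size == 0:
        raise ValueError("empty spectrum")
    if min_freq is None:
        min_freq = spectrum.resolution
    mask = spectrum.frequencies >= min_freq
    if not mask.any():
        raise ValueError(f"no bins at or above min_freq={min_freq}")
    amps = spectrum.relative_amplitudes[mask]
    return float(spectrum.frequencies[mask][int(np.argmax(amps))])
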