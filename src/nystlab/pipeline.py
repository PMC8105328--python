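"""Orchestration of the full analysis framework over a cohort of recordings.

Per subject: preprocess -> clinical summary -> segmented Fourier spectra and
dominant frequency -> threshold-crossing UPO analysis with surrogate
significance -> near-period segment -> delay embedding + principal-component
projection -> attractor classification -> sliding-window permutation
entropy; then a cross-subject entropy comparison and complexity ranking.
Partial failures are recorded per stage without aborting the cohort, and the
whole run is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attractor as _attractor
from . import clinical as _clinical
from . import entropy as _entropy
from . import spectral as _spectral
from . import upo as _upo
from .io import EyeMovementRecording, preprocess_trace

__all__ = ["AnalysisConfig", "SubjectResult", "FrameworkReport", "run_framework"]


@dataclass
class AnalysisConfig:
    """All analysis parameters in one place (YAML-loadable)."""

    oscillating_channel: str | None = None  # None: channel with largest SD
    gap_policy: str = "linear-interpolate"
    max_gap_s: float = 0.5
    target_rate: float | None = None
    detrend_window_s: float = 4.0
    prominence: float | None = None
    # spectral
    window_len: int = _spectral.DEFAULT_WINDOW_LEN
    pad: int = _spectral.DEFAULT_PAD
    hop: int | None = None
    # UPO
    upo_threshold: float = 0.0
    upo_direction: str = "rising"
    hysteresis_frac: float = 0.3
    bin_width: float = _upo.DEFAULT_BIN_WIDTH
    n_surrogates: int = _upo.DEFAULT_N_SURROGATES
    min_period: float = _upo.DEFAULT_MIN_PERIOD
    upo_alpha: float = 0.05
    segment_tolerance: float = 0.1
    segment_min_cycles: int = 3
    # embedding
    embedding_dimension: int = 7
    embedding_lag: int = 1
    n_components: int = 3
    embed_full_trace: bool = False
    # entropy
    entropy_dimension: int = 7
    T_w: float | None = None
    hop_s: float = 0.5
    comparison_alpha: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectResult:
    subject_id: str
    clinical: _clinical.ClinicalSummary | None = None
    spectra: list[_spectral.AmplitudeSpectrum] = field(default_factory=list)
    fourier_frequency: float | None = None
    upo: _upo.UPOResult | None = None
    upo_segment: _upo.UPOSegment | None = None
    projection: _attractor.ProjectedTrajectory | None = None
    attractor: _attractor.AttractorClass | None = None
    entropy: _entropy.EntropyWindowSeries | None = None
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.failures


@dataclass
class FrameworkReport:
    subjects: dict[str, SubjectResult]
    comparison: _entropy.EntropyComparison | None
    ranking: list[str]
    notes: list[str]
    config: AnalysisConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, res in self.subjects.items():
            row: dict = {"subject": sid}
            if res.clinical is not None:
                row["mean_amplitude_deg"] = res.clinical.mean_amplitude
                row["mean_frequency_hz"] = res.clinical.mean_frequency
                row["intensity_deg_hz"] = res.clinical.intensity
            row["fourier_frequency_hz"] = res.fourier_frequency
            if res.upo is not None:
                row["upo_frequency_hz"] = res.upo.frequency
                row["upo_p_value"] = res.upo.p_value
            if res.attractor is not None:
                row["attractor"] = res.attractor.label
            if res.entropy is not None:
                h = np.asarray(res.entropy.h_p_values)
                row["median_h_p"] = float(np.median(h))
                row["mad_h_p"] = float(
                    np.median(np.abs(h - np.median(h)))
                )
            if self.comparison is not None and sid in self.comparison.ranking:
                row["complexity_rank"] = self.comparison.ranking.index(sid) + 1
            row["failures"] = "; ".join(
                f"{k}: {v}" for k, v in res.failures.items()
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _pick_oscillating_channel(recording: EyeMovementRecording) -> str:
    sds = {t.channel: float(np.std(t.samples)) for t in recording.traces}
    return max(sds, key=sds.get)


def _analyse_subject(
    recording: EyeMovementRecording, config: AnalysisConfig, seed: int
) -> SubjectResult:
    res = SubjectResult(subject_id=recording.subject_id)
    channel = config.oscillating_channel or _pick_oscillating_channel(recording)
    try:
        trace = preprocess_trace(
            recording.trace(channel),
            gap_policy=config.gap_policy,
            target_rate=config.target_rate,
            max_gap_s=config.max_gap_s,
        )
    except Exception as exc:  # noqa: BLE001 - recorded, not raised
        res.failures["preprocess"] = str(exc)
        return res
    rate = trace.rate

    try:
        clean = EyeMovementRecording(
            subject_id=recording.subject_id,
            traces=[
                preprocess_trace(t, gap_policy=config.gap_policy, max_gap_s=config.max_gap_s)
                for t in recording.traces
            ],
        )
        res.clinical = _clinical.clinical_summary(
            clean,
            oscillating_channel=channel,
            prominence=config.prominence,
            detrend_window_s=config.detrend_window_s,
        )
    except Exception as exc:  # noqa: BLE001
        res.failures["clinical"] = str(exc)

    try:
        window_len = min(config.window_len, trace.n_samples)
        res.spectra = _spectral.successive_spectra(
            trace, window_len=window_len, hop=config.hop, pad=config.pad
        )
        res.fourier_frequency = _spectral.dominant_frequency(
            _spectral.mean_spectrum(res.spectra)
        )
    except Exception as exc:  # noqa: BLE001
        res.failures["spectral"] = str(exc)

    detrended = None
    try:
        upo_result, seq, detrended = _upo.upo_from_trace(
            trace,
            detrend_window_s=config.detrend_window_s,
            threshold=config.upo_threshold,
            direction=config.upo_direction,
            hysteresis_frac=config.hysteresis_frac,
            n_surrogates=config.n_surrogates,
            seed=seed,
            bin_width=config.bin_width,
            min_period=config.min_period,
            alpha=config.upo_alpha,
        )
        res.upo = upo_result
        res.upo_segment = _upo.locate_upo_segment(
            detrended,
            seq,
            period=upo_result.period,
            tolerance=config.segment_tolerance,
            min_cycles=config.segment_min_cycles,
        )
    except Exception as exc:  # noqa: BLE001
        res.failures["upo"] = str(exc)

    try:
        if detrended is None:
            raise ValueError("detrended trace unavailable (UPO stage failed)")
        if res.upo_segment is not None and not config.embed_full_trace:
            seg = detrended.samples[
                res.upo_segment.start_index : res.upo_segment.end_index + 1
            ]
        else:
            seg = detrended.samples
        emb = _attractor.delay_embed(
            seg, d=config.embedding_dimension, lag=config.embedding_lag
        )
        res.projection = _attractor.project_principal(
            emb, n_components=config.n_components
        )
        res.attractor = _attractor.classify_attractor(
            detrended.samples, rate, upo=res.upo
        )
    except Exception as exc:  # noqa: BLE001
        res.failures["attractor"] = str(exc)

    try:
        res.entropy = _entropy.sliding_entropy(
            trace.samples,
            rate,
            d=config.entropy_dimension,
            T_w=config.T_w,
            hop_s=config.hop_s,
            detrend_window_s=config.detrend_window_s,
            subject_id=recording.subject_id,
        )
    except Exception as exc:  # noqa: BLE001
        res.failures["entropy"] = str(exc)
    return res


def run_framework(
    recordings: list[EyeMovementRecording], config: AnalysisConfig | None = None
) -> FrameworkReport:
    """Run every analysis stage per recording, then compare across subjects."""
    if not recordings:
        raise ValueError("no recordings supplied")
    if config is None:
        config = AnalysisConfig()
    ids = [r.subject_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject ids: {ids}")

    seeds = np.random.SeedSequence(config.seed).generate_state(len(recordings))
    subjects: dict[str, SubjectResult] = {}
    notes: list[str] = []
    for rec, seed in zip(recordings, seeds):
        subjects[rec.subject_id] = _analyse_subject(rec, config, int(seed))

    entropy_series = [
        res.entropy for res in subjects.values() if res.entropy is not None
    ]
    comparison = None
    ranking: list[str] = []
    if len(entropy_series) >= 2:
        try:
            comparison = _entropy.compare_entropies(
                entropy_series, alpha=config.comparison_alpha
            )
            ranking = comparison.ranking
        except Exception as exc:  # noqa: BLE001
            notes.append(f"comparison failed: {exc}")
    else:
        notes.append(
            "comparison skipped: fewer than 2 subjects with valid entropy series"
        )
        ranking = [
            sid for sid, res in subjects.items() if res.entropy is not None
        ]
    return FrameworkReport(
        subjects=subjects,
        comparison=comparison,
        ranking=ranking,
        notes=notes,
        config=config,
    )
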