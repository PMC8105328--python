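"""Seeded synthetic eye-position recordings for exercising the analyses.

Three vertical-oscillation regimes are generated with known ground truth:

* ``periodic`` — an asymmetric pendular cycle (slower descending limb,
  implemented by time-warping each half-cycle), fundamental plus
  phase-locked harmonics;
* ``quasiperiodic`` — the sum of two tones with an irrational frequency
  ratio (golden ratio by default);
* ``nonperiodic`` — the x variable of a chaotic three-variable flow
  (RK4, fixed step), band-rescaled to the target amplitude and frequency.

Each trace then receives linear-plus-random-walk baseline drift, optional
Poisson saccadic intrusions (20 ms rise) and white measurement noise, all
reproducible from the seed.  The five-member cohort mirrors a clinical
layout of one periodic, one quasiperiodic and three nonperiodic subjects
with a quiet fellow eye and conjugate horizontal intrusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import EyeMovementRecording, EyeTrace, SamplingSpec

__all__ = [
    "WaveformSpec",
    "CohortMember",
    "SyntheticCohort",
    "generate_waveform",
    "generate_cohort",
    "GOLDEN_RATIO",
]

GOLDEN_RATIO = (1 + 5**0.5) / 2

REGIMES = ("periodic", "quasiperiodic", "nonperiodic")

#: Dominant frequency of the reference chaotic flow (a=0.2, b=0.2, c=5.7)
#: in model-time units, used to size the integration run.
_CHAOS_BASE_FREQ = 0.1708


@dataclass(frozen=True)
class WaveformSpec:
    """Ground-truth parameters of one synthetic oscillation."""

    regime: str
    amplitude: float = 3.0  # degrees peak-to-peak
    frequency: float = 0.5  # Hz
    asymmetry: float = 1.5  # downward/upward speed ratio (> 1: down slower)
    secondary_freq_ratio: float = GOLDEN_RATIO  # quasiperiodic only
    secondary_weight: float = 0.8
    chaos_params: tuple[float, float, float] = (0.2, 0.2, 5.7)
    drift_rate: float = 0.02  # deg/s
    intrusion_rate: float = 0.0  # events/s
    intrusion_amplitude_band: tuple[float, float] = (0.3, 1.0)
    noise_sd: float = 0.05  # degrees
    duration: float = 60.0  # seconds
    rate: float = 200.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.amplitude <= 0 or self.frequency <= 0 or self.rate <= 0:
            raise ValueError("amplitude, frequency and rate must be positive")
        if self.duration * self.rate < math.factorial(7):
            raise ValueError(
                "duration * rate must be >= 7! = 5040 samples for entropy analysis"
            )


@dataclass
class CohortMember:
    label: str
    recording: EyeMovementRecording
    spec: WaveformSpec
    oscillating_channel: str


@dataclass
class SyntheticCohort:
    members: list[CohortMember]

    @property
    def recordings(self) -> list[EyeMovementRecording]:
        return [m.recording for m in self.members]

    def member(self, label: str) -> CohortMember:
        for m in self.members:
            if m.label == label:
                return m
        raise KeyError(label)


def _periodic_cycle(spec: WaveformSpec, t: np.ndarray, phase: float) -> np.ndarray:
    # slower descending limb: down occupies r/(1+r) of each cycle
    r = spec.asymmetry
    up_frac = 1.0 / (1.0 + r)
    tau = np.mod(spec.frequency * t + phase, 1.0)
    half = 0.5 * spec.amplitude
    rising = tau < up_frac
    x = np.empty_like(tau)
    x[rising] = -half * np.cos(np.pi * tau[rising] / up_frac)
    x[~rising] = half * np.cos(np.pi * (tau[~rising] - up_frac) / (1.0 - up_frac))
    return x


def _quasiperiodic(spec: WaveformSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    x = np.sin(2 * np.pi * spec.frequency * t + p1)
    x += spec.secondary_weight * np.sin(
        2 * np.pi * spec.frequency * spec.secondary_freq_ratio * t + p2
    )
    return x * (spec.amplitude / np.ptp(x))


def _chaotic_flow(spec: WaveformSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Chaotic flow output, rescaled so its dominant frequency matches the spec."""
    a, b, c = spec.chaos_params
    h = 0.02  # model-time step, stable for the default constants
    burn = 100.0
    # generous model-time budget, refined after measuring the dominant frequency
    model_time = 2.0 * n / spec.rate * spec.frequency / _CHAOS_BASE_FREQ + 10.0
    steps = int(np.ceil((burn + model_time) / h))
    s = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)
    xs = np.empty(steps)

    def f(state: np.ndarray) -> np.ndarray:
        x, y, z = state
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    for i in range(steps):
        k1 = f(s)
        k2 = f(s + 0.5 * h * k1)
        k3 = f(s + 0.5 * h * k2)
        k4 = f(s + h * k3)
        s = s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        xs[i] = s[0]
    xs = xs[int(burn / h) :]
    xs = xs - xs.mean()
    # measure the flow's dominant frequency on the model grid
    mag = np.abs(np.fft.rfft(xs * np.hanning(xs.size)))
    freqs = np.fft.rfftfreq(xs.size, d=h)
    mag[freqs < 0.01] = 0.0
    f_model = float(freqs[np.argmax(mag)])
    # model time advances by f_model / (frequency target) slower than real time
    model_t = np.arange(n) / spec.rate * (spec.frequency / f_model)
    grid_t = np.arange(xs.size) * h
    if model_t[-1] > grid_t[-1]:
        raise ValueError("chaotic run too short for the requested duration")
    out = np.interp(model_t, grid_t, xs)
    return out * (spec.amplitude / np.ptp(out))


def _intrusion_train(
    rng: np.random.Generator,
    n: int,
    rate: float,
    events_per_s: float,
    band: tuple[float, float],
    rise_s: float = 0.02,
    hold_s: float = 0.15,
) -> np.ndarray:
    """Monophasic pulses: 20 ms ramp out, short hold, 20 ms ramp back."""
    x = np.zeros(n)
    n_events = rng.poisson(events_per_s * n / rate)
    rise = max(1, int(round(rise_s * rate)))
    hold = int(round(hold_s * rate))
    for _ in range(n_events):
        onset = rng.integers(0, max(1, n - 2 * rise - hold))
        amp = rng.uniform(*band) * rng.choice([-1.0, 1.0])
        pulse = np.concatenate(
            [np.linspace(0, amp, rise, endpoint=False),
             np.full(hold, amp),
             np.linspace(amp, 0, rise, endpoint=False)]
        )
        stop = min(n, onset + pulse.size)
        x[onset:stop] += pulse[: stop - onset]
    return x


def generate_waveform(spec: WaveformSpec, channel: str = "R_V") -> EyeTrace:
    """Generate one oscillating trace from a waveform spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    if spec.regime == "periodic":
        x = _periodic_cycle(spec, t, phase=rng.uniform(0, 1))
    elif spec.regime == "quasiperiodic":
        x = _quasiperiodic(spec, t, rng)
    else:
        x = _chaotic_flow(spec, n, rng)
    # baseline drift: linear plus a slow random walk
    x = x + spec.drift_rate * t
    x = x + np.cumsum(rng.normal(0.0, spec.drift_rate / spec.rate, n))
    if spec.intrusion_rate > 0:
        x = x + _intrusion_train(
            rng, n, spec.rate, spec.intrusion_rate, spec.intrusion_amplitude_band
        )
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, n)
    return EyeTrace(channel, x, SamplingSpec(rate=spec.rate))


def _quiet_trace(
    rng: np.random.Generator,
    channel: str,
    n: int,
    rate: float,
    noise_sd: float = 0.03,
    intrusions: np.ndarray | None = None,
) -> EyeTrace:
    offset = rng.uniform(-0.08, 0.08)  # within the 10 arcmin stability bound
    x = offset + rng.normal(0.0, noise_sd, n)
    if intrusions is not None:
        x = x + intrusions
    return EyeTrace(channel, x, SamplingSpec(rate=rate))


#: Cohort layout: (label, regime, peak-to-peak amplitude deg, frequency Hz,
#: oscillating eye).  Amplitude/frequency pairs follow the clinical table.
COHORT_LAYOUT = (
    ("subject1", "nonperiodic", 4.0, 0.5, "R"),
    ("subject2", "periodic", 2.6, 1.5, "L"),
    ("subject3", "nonperiodic", 2.5, 0.5, "L"),
    ("subject4", "nonperiodic", 2.0, 0.25, "R"),
    ("subject5", "quasiperiodic", 3.5, 1.2, "R"),
)


def generate_cohort(
    seed: int = 0, duration: float = 60.0, rate: float = 200.0
) -> SyntheticCohort:
    """Five-member synthetic cohort: 1 periodic, 1 quasiperiodic, 3 nonperiodic.

    Each member has an oscillating vertical channel in one eye, a quiet
    fellow vertical channel, and two horizontal channels carrying conjugate
    saccadic intrusions.
    """
    ss = np.random.SeedSequence(seed)
    members = []
    for child, (label, regime, amp, freq, eye) in zip(
        ss.spawn(len(COHORT_LAYOUT)), COHORT_LAYOUT
    ):
        sub_seeds = child.generate_state(2)
        spec = WaveformSpec(
            regime=regime,
            amplitude=amp,
            frequency=freq,
            duration=duration,
            rate=rate,
            seed=int(sub_seeds[0]),
        )
        osc_channel = f"{eye}_V"
        fellow_channel = "L_V" if eye == "R" else "R_V"
        rng = np.random.default_rng(int(sub_seeds[1]))
        n = int(round(duration * rate))
        osc = generate_waveform(spec, channel=osc_channel)
        fellow = _quiet_trace(rng, fellow_channel, n, rate)
        intrusions = _intrusion_train(rng, n, rate, events_per_s=0.1, band=(0.3, 1.0))
        r_h = _quiet_trace(rng, "R_H", n, rate, intrusions=intrusions)
        l_h = _quiet_trace(rng, "L_H", n, rate, intrusions=intrusions)
        recording = EyeMovementRecording(
            subject_id=label,
            traces=[r_h, osc, l_h, fellow]
            if eye == "R"
            else [r_h, fellow, l_h, osc],
            notes=f"synthetic {regime} oscillation",
        )
        members.append(
            CohortMember(
                label=label,
                recording=recording,
                spec=spec,
                oscillating_channel=osc_channel,
            )
        )
    return SyntheticCohort(members=members)
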