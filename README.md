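# nystlab

Linear and nonlinear time-series analysis of nystagmus (involuntary eye
oscillation) waveforms. The package combines a standard clinical assessment
with spectral and nonlinear-dynamics methods:

- **`nystlab.io`** — recording data model (`EyeTrace`,
  `EyeMovementRecording`), delimited-text reader/writer, gap interpolation
  and polyphase resampling.
- **`nystlab.clinical`** — per-channel position statistics, per-cycle
  amplitude/frequency, oscillation intensity (amplitude × frequency),
  fixation-stability flags, and a velocity-threshold detector for small
  saccadic intrusions.
- **`nystlab.spectral`** — segmented Fourier amplitude spectra (4000-sample
  windows, triangular taper, 1000-zero padding at each end → 0.033 Hz
  resolution at 200 Hz) and dominant-frequency extraction.
- **`nystlab.upo`** — unstable-periodic-orbit detection: threshold-crossing
  intervals, the fixed-point transform of consecutive interval triples,
  0.05 s-bin histograms, shuffled-surrogate significance testing, and
  location of the segment that best follows the detected orbit.
- **`nystlab.attractor`** — delay embedding (d = 7, lag 1),
  principal-component projection, and a quantitative attractor classifier
  (fixed point / limit cycle / torus / higher-dimensional).
- **`nystlab.entropy`** — ordinal-pattern symbolization, permutation
  entropy `H_p = −Σ P ln P` and its normalization `h_p = H_p / ln(d!)`,
  sliding-window entropy series (T_w = 25.2 s default), and cross-series
  rank-sum comparison with Bonferroni correction and complexity ranking.
- **`nystlab.synthetic`** — seeded generators for periodic (asymmetric
  pendular), quasiperiodic (two incommensurate tones) and nonperiodic
  (chaotic flow) vertical oscillations with drift, saccadic intrusions and
  measurement noise, plus a five-member cohort with ground truth.
- **`nystlab.pipeline`** — orchestration of the full framework over a
  cohort, with per-stage failure capture and a consolidated report.

## Command line

```sh
# generate the synthetic five-subject cohort as CSV recordings
nystlab simulate --seed 0 --out recordings/

# run the full framework and write per-stage artifacts + report.csv
nystlab analyse recordings/ --out results/

# re-render the consolidated report from a previous run
nystlab report results/
```

Recordings are CSV/TSV files with a `time_s` column plus any subset of
`r_h_deg`, `r_v_deg`, `l_h_deg`, `l_v_deg` (positions in degrees). Analysis
parameters can be centralised in a YAML file (`--config`); CLI flags
override it.

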