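# ptesleep

EEG analytics for rodent sleep and epileptiform activity after brain
injury. The package implements, as a tested and reusable pipeline:

- **preprocess** — EDF loading (built-in minimal EDF reader/writer),
  zero-phase Chebyshev filtering (60 Hz type-II notch, 0.5 Hz type-I
  high-pass, forward–backward), 4-s epoching, zeitgeber-time anchoring.
- **events** — high-amplitude interictal event detection (onset at 5 SD
  above the record mean, offset back below 1 SD), discrete-spike
  classification (<200 ms duration, >200 ms separation), waveform
  clustering (3 principal components + 9-component Gaussian mixture),
  per-cluster injury-specificity ratio `n_CCI/(n_CCI+n_NC)` with the
  ≥0.90 "injury-related" rule, and events-per-hour summaries.
- **sleep** — hypnogram-based architecture: time-in-state, sleep
  efficiency, bout number/length (artifact/seizure epochs excluded and
  bout-breaking), diurnal binning anchored at lights-on.
- **spindles** — cubed sigma-band (9–15 Hz) RMS envelope with 1.5×/3.5×
  selection/detection thresholds, NREM gating, and density/duration/
  amplitude/frequency/power metrics with 6-h binning.
- **spectral** — per-epoch Hann periodograms, band powers (delta
  0.5–4, theta 5–9, sigma 10–14, gamma 25–100 Hz) and normalized delta
  power with 4-h binned NREM profiles.
- **stats** — one-way ANOVA with Holm-adjusted contrasts, split-plot
  (mixed) ANOVA with Tukey–Kramer pairwise correction, Welch t-tests
  with Bonferroni doubling, hourly event-vs-wake Pearson correlation.
- **synth** — synthetic EEG/EMG cohort generator (semi-Markov
  hypnograms with diurnal modulation, state-conditioned spectra,
  injected spindles/spikes/seizures) with exact ground truth, used as
  the test bed for everything above.
- **pipeline / cli** — end-to-end orchestration with a deterministic,
  content-hashed JSON report.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: detector–oracle
equivalence on 1000 signals, the spike-rule truth table, injury-ratio
recovery over 10 seeds, spindle recovery on a 24-h record, analytic
normalized-delta checks plus group-ordering recovery, sleep-architecture
oracles, type-I-error calibration of every statistical test (1000 sims
each), and end-to-end determinism.

## CLI

```sh
# generate a synthetic cohort (EDF files + ground-truth sidecars)
ptesleep synth --config cohort.yml --out fixtures/

# full pipeline over the cohort -> JSON report (+ optional markdown)
ptesleep run --cohort fixtures/ --out report.json --markdown report.md

# single stages
ptesleep preprocess --edf fixtures/NC01.edf --out rec.npz
ptesleep sleep --hypnogram fixtures/NC01_hypnogram.csv
```

`cohort.yml` contains overrides for the `CohortConfig` fields (see
`src/ptesleep/synth.py`), e.g.:

```yaml
n_per_arm: {NC: 3, sham: 3, CCI: 4}
hours: 24.0
fs: 256.0
seed: 7
```

## Conventions

- Signals are µV; sample indices 0-based; epoch intervals half-open.
- Zeitgeber time 0 = lights-on (06:30 wall clock by default); diurnal
  bins are anchored at lights-on, so with 4-h bins, bin index 3 covers
  ZT12–16 (the first four hours of lights-off).
- Normalized delta defaults to delta/(delta+theta+sigma+gamma) and is
  therefore bounded in [0, 1] and amplitude-scale invariant; the
  delta-free denominator variant is available via `BandScheme`.
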