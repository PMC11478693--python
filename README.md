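# sensorqc

Data-quality metrics and device-confound auditing for smartphone sensor
time series.

## The problem

Remote digital-health studies collect accelerometer, gyroscope and GPS
streams from thousands of consumer-owned phones. Data quality differs
systematically between platforms — Android and iOS throttle sensors,
manage batteries and gate location access differently — and those
differences can masquerade as behavioural or clinical signal in any model
trained downstream. `sensorqc` quantifies the quality of such data with
eight formula-defined metrics, compares them across device types with
nonparametric statistics, and audits how much device identity leaks into
the metrics by trying to *predict the platform from quality alone*.

Because raw study data of this kind is rarely shareable, the package also
ships a synthetic cohort generator whose degradation profile (missingness,
noise, anomalies, sampling jitter, dispersion) is directly controllable,
with Android-like and iOS-like presets calibrated to published per-device
medians.

## The eight metrics

A *record* is one continuously sampled observation: timestamps t(n) plus
one value channel per axis. Metrics are computed per record or per
record set and aggregated to one value per (participant, sensor) by the
median.

**Completeness**

- `IRLR = n(len>1) / N` — fraction of records with at least 2 points.
- `SCR = SCC / ESCC`, `ESCC = mode(SCC)` — channels present relative to
  the modal channel count.
- `MDR = MPC / TPC`, where every consecutive gap larger than the modal
  sampling interval `ts = mode(Δt)` contributes `ceil(gap/ts − 1)` missing
  points, and `TPC` = observed + missing.

**Correctness**

- `SNR = 20·log10(MAV(x)/σ(x))` dB per channel, median over channels.
  Note the mean-absolute-value convention: a purely Gaussian record scores
  ≈ −1.96 dB, and only heavy-tailed (burst-dominated) records fall far
  below that.
- `APD = APC / TPC`, where a point is anomalous when its feature-bagging
  ensemble decision score exceeds `mean(DS) + 3·σ(DS)`. The ensemble
  scores random feature subsets (value, local z, local impulse difference
  per channel) with local-outlier-factor detectors.

**Consistency** — each is the "normalized reciprocal" `2·(1 − sigmoid(cv))`
of a coefficient of variation: `RLC` over record lengths, `SRC` over a
record's sampling intervals, `VRC` over per-record value ranges. 1 means
perfectly uniform; the score decays monotonically with dispersion.

The device audit fits a tuned random forest (stratified 70/30 split,
stratified 12-fold CV over tree count / depth / min leaf; Youden-J and
max-F operating thresholds), reports held-out metrics with percentile CIs
from repeated re-shuffled CV, compares accuracy against a label-permutation
null, and explains the model with exact TreeSHAP attributions: importance
scores `IS ∈ [0, 1]` (normalized mean |attribution|) and signed impact
levels `IL ∈ [−1, 1]` (negative → Android-like, positive → iOS-like).

## Worked example

Generate a small calibrated cohort, compute the metric table, and compare
devices:

```python
from sensorqc import synth, cohort

cfg = synth.GenConfig(n_participants=6, seed=7, sensors=("gyroscope",),
                      records_per_participant=8)
coh, _ = synth.simulate_cohort(synth.ANDROID_PROFILE, synth.IOS_PROFILE, cfg)
table = cohort.build_cohort_table(coh, seed=7)
for m in ("mdr", "snr_db"):
    r = cohort.compare_devices(table, m)
    a, i = r.group_stats["android"], r.group_stats["ios"]
    print(f"{m}: android {a['median']:.3f} ({a['iqr']:.3f})  "
          f"ios {i['median']:.3f} ({i['iqr']:.3f})  p={r.p:.3g}")
```

prints

```
mdr: android 0.417 (0.002)  ios 0.156 (0.001)  p=0.00507
snr_db: android -8.023 (0.051)  ios -13.380 (0.034)  p=0.00507
```

i.e. the Android-like profile loses ~42% of its gyroscope samples to
sampling gaps versus ~16% for iOS-like, while the iOS-like gyroscope is
much more heavily noise-dominated (−13.4 dB vs −8.0 dB), matching the
calibration targets of the presets. The Mann–Whitney p-values come from
the two-sided tie-corrected normal approximation.

The same pipeline is available from a shell:

```sh
dqm simulate --out cohort/ --seed 7 --participants 30
dqm compute  --manifest cohort/manifest.jsonl --out table.csv --seed 7
dqm stats    --table table.csv --by device
dqm classify --table table.csv --mode gyroscope --out report.json
dqm demo     --out demo/ --seed 7      # end-to-end with plots
```

## Layout

- `src/sensorqc/sensor_records.py` — record/record-set data model, CSV +
  JSON-lines manifest I/O, modal sampling interval, value ranges.
- `src/sensorqc/completeness.py`, `correctness.py`, `consistency.py` —
  the eight metrics.
- `src/sensorqc/synth.py` — synthetic cohort generator and device presets.
- `src/sensorqc/cohort.py` — participant aggregation, min-max
  normalization, Mann–Whitney / Kruskal–Wallis + Dunn + Benjamini–Hochberg.
- `src/sensorqc/devclass.py` — random-forest device audit, permutation
  null, SHAP summaries (`_treeshap.py` implements exact tree attributions).
- `src/sensorqc/cli.py` — the `dqm` command.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
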