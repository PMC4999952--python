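# vtpred

Classification of pre-ventricular-tachycardia (pre-VT) 5-minute windows
from paired ECG + respiration recordings, using 11 heart-rate-variability
(HRV) and 3 respiratory-rate-variability (RRV) parameters and a
one-hidden-layer backpropagation perceptron.

## What it does

The pipeline turns a labeled cohort of 5-minute ECG/respiration windows
into a full experiment:

1. **Peak detection** — R-peaks via a band-pass/differentiate/square/
   integrate transform with an adaptive threshold and 200 ms refractory
   period; respiration peaks via an alternating max/min delta detector.
2. **Ectopic correction** — premature beats and compensatory pauses are
   flagged with a robust running-median rule and re-estimated under the
   integrated pulse frequency modulation (IPFM) model of beat timing.
3. **HRV features** — Mean NN, SDNN, RMSSD, pNN50 (time domain);
   VLF/LF/HF/LF-HF band powers from a Welch periodogram (512-point Hann,
   50% overlap) of the 7 Hz cubic-spline tachogram after high-pass
   detrending; Poincare SD1/SD2/SD1-SD2.
4. **RRV features** — RPdM, RPdSD, RPdV from breath-to-breath periods
   after a 0.1-0.5 Hz zero-phase band-pass.
5. **Classification** — z-scored inputs, tanh hidden layer (5/5/13 units
   for the HRV/RRV/combined feature sets), linear output trained to +-1
   targets by full-batch backpropagation with an MSE < 1e-5 stopping
   rule; stratified 2/3 : 1/3 split shared across the three feature sets;
   sensitivity/specificity/accuracy/PPV/NPV, ROC and AUC.
6. **Synthetic data** — IPFM-generated RR series with LF/HF modulation
   and injected ectopic beats rendered as template ECG, plus
   variable-period respiration, calibrated so extracted cohort statistics
   match built-in per-group reference means/SDs. A feature-level
   generator draws the 14 parameters directly for fast classifier
   fixtures.

Internal units are seconds everywhere (intervals in s, band powers in
s^2, RPdV in percent).

## CLI

```sh
# simulate a 52 + 52 cohort of waveform CSVs + manifest
vtpred simulate --seed 1 --outdir cohort/

# extract the 14-parameter feature table
vtpred extract --manifest cohort/manifest.csv --out features.csv

# per-parameter group comparison (Mann-Whitney by default)
vtpred compare --features features.csv

# train / evaluate a single model
vtpred train --features features.csv --feature-set all --out model.json
vtpred evaluate --features features.csv --model model.json

# full experiment: simulate (or --manifest), extract, compare,
# train the three models on a shared split, evaluate, write reports
vtpred run --seed 1 --outdir experiment/
```

`vtpred run` also accepts a YAML config (`--config run.yaml`) with keys
`seed`, `n_per_group`, `duration`, `manifest`, `outdir`, `lr`,
`max_epochs`; command-line flags override the file.

## Layout

```
src/vtpred/
  signal_io.py       waveform + feature-table I/O, core domain types
  peak_detection.py  R-peak and delta peak detectors
  rr_preprocess.py   ectopic flagging + IPFM correction
  hrv_features.py    time-domain, spectral and Poincare parameters
  rrv_features.py    respiration band-pass + period statistics
  classifier.py      perceptron, split, metrics, ROC/AUC
  synthetic_data.py  waveform- and feature-level cohort generators
  pipeline.py        orchestration: extract, compare, train, report
  cli.py             click-based command line
tests/               pytest suite; test_acceptance.py holds the
                     acceptance criteria
scripts/acceptance.py
```
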