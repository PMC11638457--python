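# cirrdx

Automated cirrhosis diagnosis from masked multi-sequence liver MRI and serum
biomarkers, exercised end to end on synthetic phantom cohorts:

- **phantom** — seeded synthetic cohorts (liver/spleen volumes with
  controllable surface nodularity, texture and spleen enlargement; class-
  conditional serum biomarkers) written as NIfTI + CSV + manifest.
- **preprocess** — rigid NCC co-registration, 5-slice selection around the
  largest liver cross-section, percentile clipping, square padding, resizing,
  joint min-max normalization, and online training augmentation.
- **cnn** — a ResNet-18 slice-stack classifier trained with fivefold
  cross-validation (Adam, BCE, reduce-on-plateau, early stopping on
  validation AUC), probability averaging across folds, and Grad-CAM
  activation maps. Runs on a built-in numpy backend — no GPU or deep-learning
  framework required.
- **serum** — FIB-4 and APRI comparator indices.
- **fusion** — combined model: VIF screening (univariable-|β| representative
  rule for collinear groups), Gini-importance feature selection, and a
  grid-searched random forest under fivefold cross-validation.
- **evalstats** — ROC/AUC with DeLong intervals, Youden cutoffs,
  confusion-matrix metrics with exact binomial CIs, DeLong / McNemar /
  weighted-generalized-score paired comparisons, calibration tables,
  decision-curve net benefit, and subgroup AUC comparisons.

## CLI

```sh
cirrdx simulate --n 100 --prevalence 0.65 --seed 7 --out cohort/
cirrdx split --cohort cohort/ --fraction 0.9 --seed 7 --out split.json
cirrdx train --cohort cohort/ --split split.json --profile ci --out model/
cirrdx evaluate --cohort cohort/ --split split.json --model-dir model/ --out eval/
cirrdx report --scores eval/scores.csv --model-dir model/ --out report/
cirrdx report --from-counts --out report/   # published-table arithmetic only
```

Configuration is YAML (`cirrdx/data/default_config.yaml` documents every
default); `--profile ci` selects the desk-scale profile (64-px inputs, capped
epochs), `--profile parity` the full-scale one (512-px, 500 epochs).

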