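# ramanotype

Chemometric phenotyping of tomato carotenoids from handheld Raman spectra.

Tomato breeders select for fruit color, which is set by the carotenoid
profile: all-*trans*-lycopene (red), tetra-*cis*-lycopene ("tangerine"
orange), β-carotene (orange), γ-carotene, anthocyanin-rich purple skin, or
low-carotenoid (yellow/green) fruit. Reference methods (HPLC, UV-Vis after
solvent extraction) are destructive and slow. Surface Raman scans of intact
fruit offer a non-destructive alternative: carotenoids are strong Raman
scatterers with shared bands at 1007 and 1158 cm⁻¹ and a diagnostic ν1 C=C
stretching band whose position shifts with the pigment — 1519 cm⁻¹ for
all-*trans*-lycopene, 1523 cm⁻¹ for tetra-*cis*-lycopene, 1528 cm⁻¹ for
β-carotene.

This package implements the full analysis chain as scikit-learn-style
estimators, together with a seeded synthetic spectrum generator so every
stage is testable without instrument data:

- **`ramanotype.simulate`** — synthetic 512-point spectra (200–2500 cm⁻¹)
  built from concentration-scaled Lorentzian bands plus polynomial baseline,
  multiplicative scatter and shot-like noise; seven carotenoid-profile class
  recipes; a Beer–Lambert utility for UV-Vis reference concentrations
  (ε = 172 / 139 mM⁻¹cm⁻¹ for lycopene / β-carotene).
- **`ramanotype.preprocessing`** — SNV, Savitzky-Golay smoothing and
  derivatives, wavenumber-region selection, mean centering; composable as
  sklearn `Pipeline`s.
- **`ramanotype.simca`** — `SimcaClassifier`: per-class PCA submodels,
  residual F-test admission with conformal calibration, interclass distances
  (ICD) and per-wavenumber discriminating power.
- **`ramanotype.pls`** — `PLS1Regression` (NIPALS) with leave-one-out
  latent-variable selection and r/SECV/SEP reporting.
- **`ramanotype.nn`** — a from-scratch MLP (ReLU, softmax/CCE or ReLU/MSE
  heads, inverted dropout, ADAM, early stopping), sliding-window spectral
  variable selection and random hyperparameter search.
- **`ramanotype.pipeline`** — the two end-to-end experiments with seeded,
  bit-reproducible reports.

## Worked example

```python
import ramanotype as rt

report = rt.run_classification(rt.ExperimentConfig(seed=0))
print({k: report.metrics[k] for k in
       ("simca_accuracy_pct", "ann_accuracy_pct", "min_icd", "dp_argmax_cm1")})
```

prints

```
{'simca_accuracy_pct': 95.23809523809523, 'ann_accuracy_pct': 100.0,
 'min_icd': 3.811216448321985, 'dp_argmax_cm1': 1527.7886497064578}
```

106 synthetic fruit across the seven classes were simulated (three replicate
scans each, averaged), preprocessed with SNV and a 25-point second-derivative
filter restricted to 1370–1700 cm⁻¹, and classified: SIMCA assigns 95% of a
held-out 20% split to the correct class, the best MLP from a 50-trial
hyperparameter search classifies its test split perfectly, every pair of
classes is well separated (all 21 interclass distances above 3), and the
wavenumber most responsible for separating the lycopene and β-carotene
classes is 1528 cm⁻¹ — the β-carotene ν1 band.

The calibration experiment runs the same way:

```python
report = rt.run_quantification(rt.ExperimentConfig(seed=0))
print({k: round(v, 3) for k, v in report.metrics.items()
       if isinstance(v, float)})
```

```
{'pls_r_cv': 0.977, 'pls_secv_mg_per_100g': 1.246, 'pls_r_pred': 0.984,
 'pls_sep_mg_per_100g': 1.123, 'ann_r_pred': 0.938,
 'ann_rmse_mg_per_100g': 2.347}
```

58 lycopene-dominant fruit with reference concentrations uniform on
1.8–21.5 mg/100 g are calibrated by PLS1 (15-point second-derivative
pretreatment, leave-one-out latent-variable selection on an 80% calibration
set): external-validation correlation 0.98 with a standard error of
prediction of 1.1 mg/100 g. An MLP regressor tuned on a 60/20/20 split
reaches r = 0.94 on its test set.

A thin CLI mirrors the library: `ramanotype simulate`,
`ramanotype run-classification`, `ramanotype run-quantification`
(`--seed`, `--config cfg.yaml`, `--out dir`).

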