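# hccdetect

A reusable implementation of a mass-spectrometry-based blood test for
hepatocellular carcinoma (HCC).  Guideline surveillance of at-risk patients
(ultrasound ± serum alpha-fetoprotein every six months) misses many early
tumors: AFP at the common 20 ng/mL cut-off detects roughly half of cancers.
This package implements a test that combines several hundred Deep-MALDI
serum mass-spectral features with AFP in a machine-learning classifier
designed for the p >> n regime, together with everything needed to develop,
lock, apply and evaluate such a test — including a synthetic-cohort
simulator, since the original serum cohorts are proprietary.

It is intended for computational proteomics and clinical-biomarker
researchers who want to study, stress-test or extend this class of test
development procedure.

## The method

* **Spectral processing** — alignment onto anchor peaks, QC filtering,
  random selection and averaging of 140 acquisitions per sample,
  morphological background subtraction, partial-ion-current normalization,
  reference-sample batch correction, and integration over fixed m/z windows
  (the "MS features"), plus ln(AFP).
* **Classifier** — over many stratified train/test splits of the
  development set, k-nearest-neighbour *atomic* classifiers are built on
  attribute singletons and pairs, filtered (per-class training accuracy, and
  the confounder-mitigating requirement that healthy-donor spectra classify
  "No Cancer"), and combined by dropout-regularized logistic regression:
  the fit is repeated on random "leave-in" subsets of the atomics and the
  coefficients are averaged, giving one *master* classifier per split.  A
  development sample's score is the mean output of the masters that held it
  out (out-of-bag); new samples average all masters.  A threshold chosen on
  development data turns the score s ∈ [0, 1] into the binary call, and the
  model is locked before any validation.
* **Hierarchical test** — per sample, strictly in order: spectral QC gate;
  pre-classifier "Poor" → Cancer; AFP ≥ 100 ng/mL → Cancer; otherwise
  score ≥ threshold decides.
* **Evaluation** — sensitivity/specificity/accuracy by clinical subgroup,
  ROC/AUC, the DeLong test against AFP alone, AFP-cutoff comparators, and
  cumulative sensitivity by tumor size.

The model, procedure and parameters are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Develop on one half of a synthetic cohort (planted mass-spectral effect,
class-dependent AFP), lock, and blind-classify the other half:

```python
from hccdetect.workflows import run_validation_benchmark
print(run_validation_benchmark(seed=5))
```

```
{'val_sensitivity': 0.8667, 'val_specificity': 0.7833, 'auc_test': 0.9061,
 'auc_afp': 0.7306, 'delong_p': 0.00046, 'n': 120}
```

Of 120 held-out samples, the locked hierarchical test called 87% of cancers
and 78% of non-cancers correctly.  The ROC area of the test family
(classifier threshold varied; rule-assigned high-AFP samples fixed at
"Cancer") is 0.91 versus 0.73 for AFP alone, and the DeLong test for the
paired AUC difference gives p = 0.0005 — the synthetic analogue of the
published finding that the combined test significantly outperforms AFP.

A command-line interface covers the same flow on files:

```sh
hccdetect simulate --n-hcc 40 --n-no-hcc 40 --n-healthy 16 --seed 1 --out cohort/
hccdetect train --features dev.csv --healthy healthy.csv --out model.json
hccdetect classify --features val.csv --afp afp.csv --model model.json --out calls.csv
hccdetect evaluate --calls calls.csv --truth cohort/manifest.csv --out report/
```

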