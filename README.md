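# pxrml

Regularized QSAR classification for pregnane X receptor (PXR) activators.

PXR (NR1I2) is a promiscuous nuclear receptor whose activation induces
drug-metabolizing enzymes and causes drug-drug interactions. Predicting its
activators is hard precisely because its binding pocket is large and
flexible: assay collections are built from analogue series, and classifiers
tuned by ordinary cross-validated grid search learn to recognize neighbors
of their training compounds rather than general rules — they look strong in
cross-validation and fail on structurally novel chemistry.

`pxrml` is a workflow for building classifiers that hold up on unseen
chemotypes, aimed at cheminformaticians running virtual screens:

- **chemprep** — molecule standardization (largest organic fragment,
  canonical tautomer, InChI identity) and a filter cascade (weight, element,
  contradicting labels, duplicates) with an auditable per-step removal
  report that always conserves counts;
- **featurize** — 17 physicochemical descriptors and hashed circular
  fingerprints (8192-bit model fingerprints; separate 2048-bit similarity
  fingerprints), plus Tanimoto similarity;
- **selection** — grid search of random forests and RBF-SVMs under seeded
  stratified k-fold CV, scored either by mean validation MCC,

  `validation score = (1/k) Σᵢ MCC_val,i`

  or by the **gap-penalized score**, which subtracts the mean
  train-validation gap and thereby favors models whose cross-validation
  performance is not bought by memorization:

  `gap score = (1/k) Σᵢ MCC_val,i − (1/k) Σᵢ (MCC_train,i − MCC_val,i)`

- **evaluate** — applicability-domain diagnostics: per-molecule maximum
  similarity to training, MCC stratified by that similarity, chemical-space
  coverage curves, Bemis-Murcko scaffold overlap, forest complexity
  (tree heights, occupancy-weighted leaf sizes), feature-importance audits;
- **screen** — chunked library ranking by the guiding model, a unanimity
  consensus rule across an ensemble, nearest-training-neighbor reporting and
  a novelty flag for hit triage;
- **synthbench** — a synthetic analogue-series benchmark (valid, drug-like,
  ≥200 Da molecules built from ring-system templates) with class imbalance,
  series-correlated label noise, and a scaffold-held-out split, so the whole
  workflow — including the out-of-distribution claim behind the gap score —
  is testable with no downloads.

## Worked example

Compare the two selection modes on one synthetic benchmark seed (500
molecules, 20 series, scaffold-held-out OOD test):

```python
from pxrml import workflow

r = workflow.run_seed(0)
print(f"validation-mode winner : min_samples_leaf={r.rf_val_leaf}  CV MCC={r.rf_val_cv_val_mcc:.3f}")
print(f"gap-penalized winner   : min_samples_leaf={r.rf_gap_leaf}  CV MCC={r.rf_gap_cv_val_mcc:.3f}")
print(f"IID test MCC           : validation {r.rf_val_iid_mcc:.3f} | gap {r.rf_gap_iid_mcc:.3f}")
print(f"OOD test MCC           : validation {r.rf_val_ood_mcc:.3f} | gap {r.rf_gap_ood_mcc:.3f}")
print(f"median tree height     : validation {r.rf_val_median_height:.0f} | gap {r.rf_gap_median_height:.0f}")
```

```
validation-mode winner : min_samples_leaf=1  CV MCC=0.813
gap-penalized winner   : min_samples_leaf=8  CV MCC=0.759
IID test MCC           : validation 0.900 | gap 0.798
OOD test MCC           : validation 0.621 | gap 0.658
median tree height     : validation 8 | gap 5
```

Classical selection picks the deepest forest (leaf size 1) and wins
cross-validation and the in-distribution test; the gap-penalized mode picks
a visibly simpler forest (leaf size 8, shallower trees) that comes out ahead
on the scaffold-held-out compounds — the ones a prospective screen cares
about.

The same steps are available from the shell:

```bash
pxrml simulate --n-scaffolds 20 --analogues 25 --seed 0 --out bench/
pxrml prep --input raw.csv --dialect user --min-mw 200 --out clean/
pxrml train --input bench/train.csv --features pc+fp --algorithm rf --scoring gap --seed 0 --out model.joblib
pxrml eval --model model.joblib --train bench/train.csv --test bench/ood_test.csv --out eval/
pxrml screen --library library.csv --guiding model.joblib --train bench/train.csv --out hits.csv
```

Real assay exports (PubChem AID 720659 CSVs, ToxCast summary files with
`hitc_cis_up`/`hitc_trans_up` columns, literature SD-derived tables) are
consumed with the matching `--dialect`; nothing is fetched from the network.

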