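# triazine-qsar

QSAR regression modeling and auditing for a panel of 32 1,2,4-triazin-3(2H)-one
derivatives assayed as microtubule-assembly inhibitors against the MCF-7
breast-cancer cell line, plus 28 designed candidate compounds.

Activity is expressed as pIC50 = −log10(IC50, mol/L) and modeled by ordinary
least squares on five molecular descriptors:

    pIC50 = b0 + b1·χ + b2·TE + b3·NHD + b4·LogS + b5·I

with χ the absolute electronegativity, TE the quantum-chemical total energy,
NHD the hydrogen-bond-donor count, LogS the log aqueous solubility, and I a
binary shape indicator. The package implements, as a tested library:

- **Fitting and selection** (`mlr`): OLS with full-rank checking, backward
  descriptor elimination (drop-largest-p-value at α, then a VIF screen),
  variance inflation factors.
- **Validation** (`validation`): R², adjusted R², residual mean square, Fisher
  F, leave-one-out Q² (PRESS), external-set R², the Golbraikh–Tropsha
  through-origin slopes k/k′ and R0²/R0′², the Ojha Rm² metrics, and the
  combined pass/fail checklist.
- **Y-randomization** (`randomization`): seeded response scrambling with
  averaged null statistics and cRp² = R·√(R² − (mean R_rand)²).
- **Applicability domain** (`domain`): hat-matrix leverage, the warning
  threshold h* = 3(k+1)/n, standardized residuals, Williams-plot export.
- **Candidate screening** (`screening`): ranked activity predictions with
  leverage flags for designed compounds.
- **Synthetic data** (`simulate`): a seeded generator with the study-like
  linear truth for parameter-recovery and selection benchmarks.

The 32 study compounds and 28 designed candidates ship as packaged CSVs
(descriptors, observed activity, and the originally published predictions);
`load_study_data()` returns them as typed objects.

## Worked example

```python
from triazine_qsar import (DESCRIPTOR_NAMES, fit_ols, load_study_data,
                           validate_model, run_y_randomization, assess_domain)

dataset, candidates = load_study_data()
model, diag = fit_ols(dataset, DESCRIPTOR_NAMES)
print(validate_model(dataset, model).render_table())
```

prints (abridged):

```
parameter        value  threshold   verdict
R                0.849
R2               0.721  > 0.6       passed
Q2_LOO           0.540  > 0.5       passed
R2_test          0.735  > 0.6       passed
k                0.996  0.85..1.15  passed
k'               0.997  0.85..1.15  passed
rm2 mean         0.361  > 0.5       FAILED
rm2 delta        0.002  < 0.2       passed
```

R² ≈ 0.72 means the five descriptors explain ~72 % of the activity variance
across the 27 training compounds; Q² ≈ 0.54 > 0.5 indicates the model survives
leave-one-out cross-validation; k, k′ ≈ 1 say the observed-vs-predicted
through-origin regressions on the 5 test compounds have near-unit slope. The
Rm²-mean failure is a genuine feature of this dataset's test split (the
observed/predicted correlation on the 5 test compounds is *negative*; see
`docs/methods.md`).

The numbered drivers under `analysis/` run the full study end to end and
write tables to `results/`:

```
python analysis/01_fit_model.py          # coefficients + VIF
python analysis/02_validate_model.py     # validation table + checklist
python analysis/03_y_randomization.py    # 100 scrambles, cRp2
python analysis/04_applicability_domain.py  # Williams plot, 0 of 32 outliers
python analysis/05_screen_candidates.py  # 28 ranked candidates
python analysis/06_synthetic_benchmark.py
```

For example, `03_y_randomization.py` prints mean scrambled statistics
R_rand ≈ 0.44, R²_rand ≈ 0.21, Q²_rand ≈ −0.34 — far below the real model's
0.85 / 0.72 / 0.54 — and cRp² ≈ 0.62 > 0.5, i.e. the model is not a chance
correlation. `05_screen_candidates.py` shows that the most active designed
candidates (predicted pIC50 up to ~9.9) also carry leverage far above
h* = 0.5625: their activities are extrapolations beyond the training panel's
descriptor space.

There is also a CLI mirroring the drivers:

```
triazine-qsar fit --out out/
triazine-qsar randomize --seed 7 --n 100 --out rand.json
triazine-qsar screen --out screening.csv
triazine-qsar simulate --seed 3 --out synthetic.csv
```

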