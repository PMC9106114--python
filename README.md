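# vcgkit

Derived vectorcardiography (VCG) from the 12-lead ECG, with a
statistical pipeline for ranking transformation methods by accuracy.

## The problem

The Frank orthogonal lead system measures the heart's electrical dipole
directly on three perpendicular leads X, Y, Z, but is rarely recorded in
clinical practice. Instead, orthogonal leads are *derived* from the
routinely acquired 12-lead ECG by a fixed linear map

```
VCG_der = M · E
```

where `E` stacks the eight independent ECG leads (I, II, V1–V6) and `M`
is a published 3×8 coefficient matrix. Which matrix to trust matters
most on pathological records (e.g. myocardial infarction), where the
transforms are least accurate. vcgkit implements the commonly compared
methods —

* **Kors** regression matrix,
* **IDT**, the inverse Dower transform,
* **QLSV** / **PLSV** least-squares matrices (QRS- and P-wave optimised),
* the **quasi-orthogonal** shortcut `X = V6, Y = II, Z = −0.5·V2`,
* plus the Frank resistor-network synthesis from raw electrode
  potentials —

and scores each method per lead by the mean squared error against a
directly measured reference VCG,

```
MSE = (1/n) Σᵢ (Vᵢ − oVᵢ)²     [mV²]
```

computed over the whole baseline-corrected record. Accuracy ranking is
then a nonparametric cascade: Shapiro–Wilk normality per cell,
Kruskal–Wallis across methods per lead, Dunn's post-hoc z-tests when
Kruskal–Wallis rejects, and a compact letter display in which methods
sharing a letter are not statistically separated at α = 0.05.

A seeded generator produces paired synthetic (ECG, VCG) cohorts —
Gaussian-wavelet beats on a rotating dipole, projected to the ECG leads
through the pseudoinverse of the IDT matrix, with baseline wander and
broadband noise, and an optional infarction-like morphology (ST offset,
T inversion) — so the whole pipeline runs end-to-end with no database
download. Real records (e.g. PTB from PhysioNet) can be analysed via
CSV, or WFDB with the optional `wfdb` extra.

## Worked example

```python
import vcgkit as vk

cfg = vk.CohortConfig(n_records=30, seed=1)        # 10 s records @ 1 kHz
pairs, _ = vk.generate_cohort(cfg)                 # paired (ECG, VCG)
table = vk.evaluate_cohort(pairs)                  # per-lead MSE, 360 rows
table = vk.flag_outliers(table)                    # Tukey fences, rows kept
results = vk.MethodComparison(table).fit(alpha=0.05)
print(results.summary())
```

prints

```
Transformation-method accuracy comparison
alpha = 0.05, p-adjustment = none
==========================================================
Lead X:
  Kruskal-Wallis Q = 103.8019, df = 3, p = 2.365e-22  (reject H0)
  Shapiro-Wilk idt: p=0.0104, kors: p=0.172, qlsv: p=0.0976, quasi: p=0.0869
  order (median MSE, homogeneous groups):
    1. idt     8.88916e-05 mV^2   a
    2. kors    0.000748101 mV^2   b
    3. qlsv     0.00148447 mV^2   c
    4. quasi    0.00178484 mV^2   c
----------------------------------------------------------
...
```

Reading: on lead X the Kruskal–Wallis test rejects equal median MSE
across the four methods; IDT alone carries letter `a` (most accurate
homogeneous group), Kors is next, and QLSV/quasi share a letter, i.e.
they are statistically indistinguishable from each other. IDT winning
is a property of this synthetic generator (its forward projection is
the pseudoinverse of IDT, so IDT is exact up to noise); on real
infarction records the published evidence favours the Kors matrix —
see `docs/methods.md`.

The same run from a shell:

```sh
vcgkit run --seed 1 --out run/        # simulate + evaluate + report
vcgkit simulate --out cohort/ --seed 1
vcgkit evaluate --ecg-dir cohort/ --vcg-dir cohort/ --out mse.csv
vcgkit report --mse mse.csv --out report/
```

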