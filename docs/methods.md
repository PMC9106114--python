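# Methods

## Signal model

A record is a uniformly sampled matrix of simultaneous lead voltages in
mV with a single sampling rate (default 1 kHz, the PTB convention).
The eight independent ECG leads are I, II and V1–V6; the remaining limb
leads are derived algebraically (III = II − I, aVR = −(I+II)/2,
aVL = I − II/2, aVF = II − I/2) and are never inputs to a
transformation matrix, because including linearly dependent channels
would make the published 3×8 matrices ill-defined.

## Lead transformations

Every derivation is samplewise linear: `VCG_der[t] = M · E[t]`. The
Kors, inverse-Dower (IDT), QLSV and PLSV coefficient matrices are
stored verbatim from their original publications (Kors et al. 1990;
Edenbrandt & Pahlm 1988; Guillem et al. 2008) and are exportable to CSV
for audit. The quasi-orthogonal rule (X = V6, Y = II, Z = −0.5·V2) is
implemented both directly and as a sparse matrix; both paths are tested
for samplewise equality. The Frank synthesis maps the seven electrode
potentials (I, E, C, A, M, F, H) through the resistor-network weights

```
Px = 0.610A + 0.171C − 0.781I
Py = 0.655F + 0.345M − 1.000H
Pz = 0.133A + 0.736M − 0.264I − 0.374E − 0.231C
```

PLSV is provided but excluded from the default four-method comparison
(`kors, idt, qlsv, quasi`), mirroring how the method set is normally
compared on infarction data.

### Forward projection

The simulator projects VCG → ECG through `F = pinv(M_IDT)`, an 8×3
matrix satisfying `M_IDT · F = I₃` exactly (IDT has full row rank).
This is a deliberate design choice over transcribing Dower's historical
forward matrix: it gives the pipeline an analytic oracle — in the
noiseless limit IDT recovers the generating VCG to floating-point
precision — at the cost of making IDT the best method *by construction*
on synthetic cohorts. Consequently the ranking test asserts the
generator-consistent order (IDT in the top letter group), **not** the
order reported on real myocardial-infarction records, where regression
matrices fitted to measured data (Kors) win. Conclusions about real
data should come from running the pipeline on real paired records.

## Baseline-wander removal

Baseline wander (respiration, electrode motion; ≲0.5 Hz) is estimated
per lead by a Savitzky–Golay smoother and subtracted. Defaults: window
1.2 s — 1201 samples at 1 kHz, scaled as `round_to_odd(1.2·fs)` for
other rates because the window length must be odd — and polynomial
order 3, a standard trend-estimation choice; both are configurable.
Edges are handled by polynomial fits on the terminal window
(`mode="interp"`), so output length equals input length. The smoother
is linear, reproduces constants and straight lines exactly, and its
effective cutoff (≈1 Hz at the default settings) leaves the QRS complex
essentially untouched while capturing >90 % of sub-0.2 Hz drift power.

Both arms — the transformed ECG and the reference Frank leads — pass
through the same correction before comparison (switchable via
`correct_reference`). Aligning both arms avoids charging reference
drift to the transforms, and because the smoother is the same linear
time-invariant operation on every channel, it commutes with any lead
matrix; this is what preserves the exact noiseless IDT recovery through
the full pipeline.

## Synthetic cohort generator

Each beat is a sum of five Gaussian wavelets (P, Q, R, S, T) per axis
with per-(wave, axis) amplitude, centre and width; the default
amplitudes are adult-scale Frank magnitudes (R ≈ 1.0/0.6/−0.4 mV on
X/Y/Z) at 72 bpm with fixed RR intervals. Centres differ by 5–10 ms
across axes to emulate the rotation of the QRS and T loops; without
this the three leads would be combinations of shared bump functions, a
degenerate geometry in which a non-identity composite matrix can cancel
pointwise and the between-method ordering becomes an artifact.

The ECG channels receive a per-lead random-phase sinusoid (default
0.3 mV at 0.25 Hz) and i.i.d. Gaussian noise (default 0.02 mV);
between-record variance comes from a seeded uniform ±20 % per-wave
amplitude jitter. The infarction-like option adds a constant ST-segment
offset (default +0.1 mV, applied between 3σ past the S centre and 3σ
before the T centre with 10 ms cosine ramps) and flips the T-wave sign.
These morphology defaults are modelling choices, not measured values.

Cohort defaults are the study conditions: 30 records at 1 kHz, four
methods, α = 0.05. Record duration defaults to 10 s (the statistics of
per-record MSE stabilise well below the 120 s of archival records, and
this keeps a full pipeline run at a few seconds); 120 s is available
via `duration_s`.

What the generator does **not** emulate: heart-rate variability,
respiration-modulated amplitudes, electrode-motion artifacts, powerline
interference, realistic infarction stage morphology, and any
inter-subject correlation structure. Passing tests therefore certify
the pipeline's arithmetic, calibration and invariances — not clinical
transform accuracy.

Determinism: all randomness flows through `numpy.random.SeedSequence`
keyed by (seed, CRC32(record_id)), so any record can be regenerated
independently and whole runs are bit-reproducible.

## Accuracy statistic and outlier screening

MSE is computed over the full preprocessed record, not per beat. Remote
observations are screened per (method, lead) group with Tukey inner
fences, `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, quartiles by linear
interpolation between order statistics (the convention is pinned so the
fence test is reproducible); flagged rows are *retained* — biological
MSE data legitimately contain extreme values. Groups smaller than 4 are
not fenced.

## Statistical cascade

* **Shapiro–Wilk** per (method, lead) cell via Royston's AS R94
  algorithm (scipy implementation). Reported, and by default not
  gating: MSE data are right-skewed and the nonparametric path is
  taken regardless; `gate_on_normality=True` enforces gating, and
  `pooled_normality=True` tests the lead's pooled sample instead.
* **Kruskal–Wallis** on pooled mid-ranks:
  `Q = −3(n+1) + 12/(n(n+1)) Σ Tᵢ²/nᵢ`, divided by the tie correction
  `1 − Σ(t³−t)/(n³−n)`; p from χ² with k−1 df. The pooled rank-sum
  identity Σranks = n(n+1)/2 is asserted internally on every call.
  With no ties the corrected and uncorrected forms coincide. A warning
  fires when any group has fewer than 5 observations, where the χ²
  approximation degrades: at total n = 15 its p-value can differ from
  the exact permutation p by up to ≈0.05, which bounds how tightly any
  χ²-referenced p can be validated at that size.
* **Dunn post-hoc** when Kruskal–Wallis rejects:
  `z_ij = (R̄ᵢ − R̄ⱼ)/√(S²(1/nᵢ + 1/nⱼ))` with the tie-corrected rank
  variance `S² = n(n+1)/12 − Σ(t³−t)/(12(n−1))`; two-sided normal
  p-values. Multiplicity adjustment defaults to `none` (pairwise
  decisions at α, the common reading of Dunn tables in this
  literature), with `bonferroni` and `holm` available.
* **Compact letter display** by insert-and-absorb: start from one group
  holding all methods; each significant pair splits every group
  containing both; subset groups are absorbed. The result guarantees
  two methods share a letter iff they are not separated at α (verified
  exhaustively against a brute-force assigner for every k = 4
  significance pattern). Letters are ordered by each group's best
  median, so `a` always tags the most accurate homogeneous group.

Degenerate inputs (constant samples, all-tied groups) raise a dedicated
error rather than returning meaningless statistics.

## Numerical choices

* Quartiles: linear interpolation (`numpy.quantile` default).
* Ranks: mid-ranks for ties (`scipy.stats.rankdata`, "average").
* Tail probabilities: `scipy.stats.chi2.sf` / `norm.sf`, reported at
  full double precision.
* The exactness oracle `M_IDT · pinv(M_IDT) = I₃` holds to ≤1e-10 per
  entry and underwrites the ≤1e-20 mV² noiseless-recovery bound.

## Known limitations

* Transform matrices are population-level constants; no patient-specific
  fitting.
* The generator's linear ECG–VCG consistency means synthetic rankings
  say nothing about which method is best on real pathological data.
* WFDB ingestion is a thin optional adapter (requires `wfdb`); only the
  CSV path is exercised by the test suite.
* No beat detection or per-beat analysis; MSE over the whole record
  weights all cardiac phases by duration, matching the evaluation
  design this package implements.
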