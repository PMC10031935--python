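# seroprog

Serum immuno-oncology panel prognostication for metastatic breast cancer
(MBC) cohorts.

Newly diagnosed MBC patients differ widely in outcome, and circulating
serum proteins measured before first-line therapy are candidate prognostic
markers. `seroprog` implements, as a tested and reusable pipeline, a
workflow for mining a multiplex serum panel (92 immuno-oncology proteins on
Olink's log2 NPX scale) for markers of overall survival (OS) and
progression-free survival (PFS):

1. **NPX preprocessing** — sample-exclusion accounting, removal of proteins
   and samples with more than 15% of measurements below the limit of
   detection (LOD), rescaling by subtracting the per-protein LOD with deep
   below-LOD values (below LOD − 2·SD) set to NA, and kNN imputation
   (k = 5).
2. **Covariate residualization** — per-protein OLS on the eight established
   clinical prognostic factors (age, ECOG, metastasis-free interval, number
   of metastatic sites, site of metastasis, subtype, NHG, CTC ≥ 5), so the
   forests rank proteins on signal the clinic does not already explain.
3. **Cascaded feature selection** — an untuned random-survival-forest
   prescreen drops the 25% of proteins with the lowest median permutation
   importance and passes the top 20 forward; a randomized grid with
   repeated 5-fold cross-validation tunes the forest; repeated 10-fold CV
   yields train/test concordance; recursive feature elimination (RFE) over
   the importance-ordered top 20 selects the marker count that maximizes
   the median test Harrell's C.
4. **Validation** — classical Cox models (univariable and adjusted) with
   per-doubling hazard ratios, Benjamini–Hochberg q-values over the full
   assayed panel, elastic-net penalized Cox on residualized and raw data,
   and cross-model rank-concordance tables.
5. **Clinicopathological associations** — each selected marker is
   dichotomized at its median and tested against clinical features with
   Fisher's exact test (two-level features) or logistic regression
   (multi-level features).

Because patient-level serum cohorts of this kind are rarely public, the
package ships a first-class **synthetic-cohort generator**
(`seroprog.cohort`): correlated log2 NPX blocks, LOD truncation, Table-1
style clinical covariates, and Weibull proportional-hazards OS/PFS outcomes
with planted per-doubling log hazard ratios and calibrated right censoring.
Every downstream stage is testable against this generator's known truth.

## The model

For a protein with abundance $x$ in log2 NPX units (one unit = one doubling
of protein content), the Cox proportional-hazards model

$$\lambda(t \mid x) = \lambda_0(t)\, e^{\beta x}$$

gives $e^{\beta}$ as the hazard ratio **per doubling** of serum
concentration. The random survival forest is the canonical
log-rank-splitting ensemble: each bootstrap tree splits nodes by the
standardized two-group log-rank statistic $(O-E)^2/V$, leaves carry
Nelson–Aalen cumulative hazards $\hat H(t)=\sum_{t_k\le t} d_k/n_k$, and a
sample's risk score is the ensemble mortality (the ensemble cumulative
hazard summed over the training event-time grid). Discrimination is
Harrell's C: the probability that of a usable pair, the sample that died
sooner had the higher predicted risk. P values use the two-threshold
evidence convention (suggestive 0.005 ≤ P < 0.05, significant P < 0.005);
q-values are Benjamini–Hochberg with the full panel (m = 92) as the family.

## Worked example

```python
import numpy as np
from seroprog import CohortConfig, generate_cohort, PanelPrognosisModel

config = CohortConfig(
    n_samples=150,
    planted_effects={"P001": (np.log(2.0), np.log(2.0)),   # harmful marker
                     "P025": (np.log(0.5), np.log(0.5))},  # protective marker
    censoring_rate=0.3,
    seed=7,
)
cohort = generate_cohort(config)
model = PanelPrognosisModel.from_cohort(cohort)
results = model.fit(profile="desk", seed=1, endpoints=("OS",))
print(results.summary())
```

prints

```
Serum panel prognostication
========================================
samples analyzed: 150; proteins retained: 92

[OS] median train C = 0.858, median test C = 0.733
[OS] selected markers (14): P005, P025, P001, P020, P042, P037, P014, P064, P060, P049, P087, P085, P044, P040
         HR_uv  P_uv  q_uv  HR_mv  P_mv  q_mv
protein
P005     1.609 0.000 0.002  1.627 0.000 0.005
P025     0.618 0.000 0.002  0.566 0.000 0.001
P001     1.502 0.000 0.007  1.543 0.001 0.017
P020     0.749 0.012 0.151  0.749 0.017 0.225
...
```

Both planted markers are recovered: P001 (planted per-doubling HR 2.0,
attenuated to ≈1.5 marginally by its correlation block and frailty) and
P025 (planted 0.5, recovered 0.62), with small q-values against the
92-protein family. P005 sits in P001's correlation block and inherits a
marginal association — exactly the behavior a correlated panel produces.
The test C of ≈0.73 reflects the strong planted effects; a null panel
scores ≈0.5.

The same cascade is scriptable stage by stage (`seroprog simulate`,
`seroprog preprocess`, `seroprog all --indir ... --outdir ...`), writing a
deterministic report bundle: Cox tables with HR/CI/P/q per endpoint, the
RFE curve, importance tables, rank-concordance and association tables, and
a JSON manifest. Two runs with the same config and seed produce
byte-identical bundles.

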