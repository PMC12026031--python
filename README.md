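# csfrisk

CSF-biomarker dementia-risk scoring for memory-clinic cohorts: the
**Erlangen Score** (ERS) versus the **pTau181/Aβ1-42 ratio**, compared on
their ability to predict cognitive decline and conversion to dementia.

## Who this is for

Clinical neurochemists and biostatisticians working with cerebrospinal
fluid (CSF) biomarker panels — Aβ1-42, Aβ1-40, pTau181, total tau — who
need a tested, reproducible pipeline for

1. classifying biomarker profiles into ATN(R) constellations and ordinal
   risk scores,
2. calibrating assay-specific pTau/Aβ1-42 cut-offs,
3. modelling longitudinal MMSE z-score trajectories by risk group, and
4. comparing risk scores on time-to-dementia discrimination.

Because patient-level memory-clinic data are not freely shareable, the
package includes a first-class synthetic cohort generator that emulates
the statistical structure of such a cohort, so every pipeline stage is
testable end to end.

## The scores

**Erlangen Score** (ordinal, 0–4). Each marker is scored against its
assay cut-off with a ±10 % borderline band: clearly normal = 0,
borderline = 1, clearly pathological = 2. The amyloid sub-score (from
Aβ1-42, pathological when low) plus the tau sub-score
(max of the pTau181 and tTau zone scores, pathological when high) give a
sum in 0–4; the Aβ1-42/Aβ1-40 ratio then adds +1 (pathological, i.e.
below its cut-off) or −1 (normal), and the result is clamped back into
[0, 4]. Totals above 1 are "suspicious for Alzheimer's disease" (high
risk). Without the ratio the unadjusted sum is read as low (0–1) /
medium (2) / high (3–4).

**pTau/Aβ1-42 ratio** (binary). The quotient pTau181 / Aβ1-42 is
compared with an assay-specific threshold calibrated by maximizing
Youden's J = sensitivity + specificity − 1 over neurochemically definite
AD cases (all four markers clearly pathological) versus
biomarker-negative controls.

**Comparison machinery.** MMSE z-score trajectories are fitted with the
linear mixed model

    zMMSE_it = β0 + β1·t + β2·group_i + β3·(group_i × t) + u0_i + u1_i·t + e_it

with random intercept/slope and AR(1) within-subject residuals,
estimated by exact maximum likelihood (AIC/BIC and marginal/conditional
RMSE for model comparison). Conversion risk is assessed by converting
each score into a 10-year conversion probability via a Cox proportional
hazards model (Breslow baseline), feeding ROC/AUC analysis, with
correlated AUCs compared by the paired DeLong test, plus 2×2 diagnostic
summaries (sensitivity, specificity, likelihood ratios, diagnostic odds
ratio).

## Worked example

```python
from csfrisk import CsfProfile, ers_total
from csfrisk.cohort import DEFAULT_PANEL

subject = CsfProfile("p001", ab42=800.0, ptau=75.0, ttau=520.0,
                     ab40=800.0 / 0.042)
res = ers_total(subject, DEFAULT_PANEL)
print(res.amyloid_subscore, res.tau_subscore, res.ratio_adjustment,
      res.total, res.risk_class)
```

prints `0 2 1 3 high`: Aβ1-42 is clearly normal (0 points), both tau
markers are clearly elevated (2 points), and the pathological
Aβ1-42/Aβ1-40 ratio (0.042 < 0.05) adds one — total 3, high dementia
risk even though Aβ1-42 alone looks normal. This R+A−T+N+ profile is
exactly the constellation on which the ERS and the pTau/Aβ1-42 ratio
disagree most in practice.

The same flow from the shell, on a fully synthetic cohort:

```sh
csfrisk simulate --seed 1 --out-dir cohort/
csfrisk report --biomarkers cohort/biomarkers.csv \
               --visits cohort/visits.csv \
               --outcomes cohort/outcomes.csv \
               --out-dir report/
```

`report/report.json` then contains the constellation × score cross-tab,
the mixed-model comparison table (AIC/BIC/RMSE per grouping scheme), the
Cox-calibrated AUC per score, paired DeLong tests, and the diagnostic
2×2 summaries.

## Layout

| module | contents |
| --- | --- |
| `csfrisk.panels` | assay panels, CSF profiles, three-zone classification, ATN(R) constellations |
| `csfrisk.ers` | Erlangen Score with/without the amyloid-ratio adjustment |
| `csfrisk.ptau_ratio` | pTau/Aβ1-42 ratio, Youden-index calibration, classification |
| `csfrisk.lmm` | mixed-model likelihood, ML fitting, RMSE, model comparison |
| `csfrisk.risk` | Cox calibration, ROC/AUC, DeLong test, diagnostic tables |
| `csfrisk.cohort` | synthetic cohort generator and the deterministic fixture |
| `csfrisk.io` / `csfrisk.pipeline` / `csfrisk.cli` | table I/O, end-to-end report, command line |

See `docs/methods.md` for the statistical details and design choices.
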