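# mirstab

Longitudinal stability analysis of plasma miRNA qPCR panels.

Circulating miRNAs are attractive minimally-invasive biomarkers, but a
candidate marker is only useful if its level in a healthy person is stable
across repeated blood draws and measurable above the technical noise of
plasma qPCR. `mirstab` implements an end-to-end analysis for longitudinal
plasma miRNA panels profiled on qPCR array cards (hundreds of assays per
draw, biweekly draws per donor): reaction-level QC with explicit censoring,
longitudinal coverage filtering, hemolysis scoring, exogenous spike-in and
batch calibration, a censoring-aware multilevel normalization, per-miRNA
stability indexing, and ridge-based quantification of confounder effects.
It is written for analysts running test–retest biomarker studies, and ships
a seeded synthetic-study generator with full ground truth so every stage is
testable without access to raw study data.

## The model

Each qPCR reaction yields a quantification cycle Cq (one cycle ~ one log2
unit of expression; lower Cq = more abundant). A reaction is *acceptable*
when AmpScore >= 1, CqConf >= 0.8 and Cq < 34; *censored* when QC passes but
Cq >= 34 (the true value lies between the recorded Cq and the instrument
maximum of 40); otherwise *missing*. The pipeline then:

1. keeps miRNAs whose mean longitudinal coverage across donors is at least
   1 − 1/e ≈ 63.2% (the threshold approximating greedy coverage selection);
2. scores hemolysis per draw as Cq(miR-23a-3p) − Cq(miR-451a) (> 7 =
   appreciable red-cell lysis);
3. median-aligns all samples on an exogenous calibration factor — the
   average of the duplicate cel-miR-39-3p spike-in mean and the median Cq
   of the always-observed miRNAs — then removes processing-sequence trends
   (Nadaraya–Watson smoother, leave-one-out bandwidth) and RNA-isolation
   batch effects (REML mixed model; batch BLUPs subtracted);
4. normalizes each miRNA *m* with a multilevel interval regression

       Cq_mpv = β0 + β1·miR16_pv + β2·set1_pv + β3·set2_pv + β4·hem_pv
                + b_p + ε,      b_p ~ N(0, σ_b²),  ε ~ N(0, σ²),

   where acceptable values enter the Gaussian likelihood exactly, censored
   values as the interval [calibrated Cq, 40] and missing values as
   (40, ∞); the random intercept b_p carries the donor's level. Every visit
   sample receives a definite normalized Cq and a standard error;
5. indexes stability per miRNA: within-subject trend over the visit
   sequence (cluster-robust/sandwich variance over donors), drift re-
   expressed as % change in expression per month via 2^(−Cq), and the
   residual variance decomposed into a between-participant SD and the
   test–retest SD — the key reliability index, with SD < 1.0 log2 units on
   both axes defining a *stable* miRNA. A supremum scan over candidate
   breakpoints locates the mean-Cq threshold separating low- from
   high-dropout miRNAs;
6. quantifies measurement bias (visit-level deviations vs five time-varying
   factors) and test–retest variance moderation (donor-level log2-SD vs
   seven donor-level factors) with per-miRNA cross-validated ridge
   regressions; effects at or beyond log2(1.5) ≈ 0.58 are counted as large.

## Worked example

```python
from mirstab import SimulationConfig, run_pipeline

result = run_pipeline(sim_config=SimulationConfig(), seed=1)
s = result.summary
print(s["n_samples"], s["n_retained"], s["n_always_observed"],
      s["n_stable"], round(s["breakpoint_cq"], 2))
print({k: round(v, 2) for k, v in result.variance_audit.items()})
```

prints

```
136 110 64 49 29.55
{'raw': 0.85, 'spikein_aligned': 0.21, 'sequence_detrended': 0.21, 'batch_adjusted': 0.21}
```

i.e. of 378 assays on the card, 110 miRNAs pass the 63.2% coverage filter in
this synthetic study, 64 are observed in every one of the 136 draws, and 49
are stable (both SDs < 1.0). The dropout breakpoint sits near Cq 29.6, and
spike-in alignment removes about three quarters of the shared technical SD
(0.85 → 0.21 cycles) while batch adjustment changes almost nothing — batch
shifts are already tracked by the spike-in. The same pipeline runs from a
directory of per-participant instrument exports via
`mirstab run --input-dir DIR --out OUT`, and `mirstab simulate` writes a
synthetic study in that export dialect together with its ground truth.

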