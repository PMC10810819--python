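# Methods

This note documents the statistical procedures implemented in `mirstab`,
the assumptions they rest on, the design choices made where the design was
genuinely open, and what the synthetic-study generator does and does not
emulate.

## Reaction QC and censoring

A qPCR reaction is classified from its instrument QC metrics: *acceptable*
if AmpScore ≥ 1, CqConf ≥ 0.8 and Cq < 34 cycles; *censored* if QC passes
but Cq ≥ 34 (the recorded value is a lower bound; the instrument maximum is
40); *missing* if QC fails or no Cq was recorded ("Undetermined"),
regardless of any recorded value. All four constants are configuration
values (`QCConfig`) with these defaults, and thresholds are inclusive.
Classification is total: every well receives exactly one status, and no
later stage ever changes it.

## Coverage filtering

Coverage of an assay for a donor is the fraction of that donor's analyzed
visits with an acceptable Cq; the filter keeps assays whose unweighted mean
across donors is at least 1 − 1/e ≈ 63.2%, the threshold that approximates
greedy sequential selection by average-coverage improvement. The greedy
algorithm itself is deliberately not implemented — the operative published
rule is the threshold. Donors are weighted equally regardless of visit
count, and denominators use the visits actually analyzed. The
*always-observed* set (acceptable in 100% of all samples) anchors the
calibration factor; an empty set is a hard error because the factor is then
undefined.

## Hemolysis score

Red-cell lysis releases erythrocyte miRNAs (notably miR-451a) into plasma;
the per-sample score Cq(miR-23a-3p) − Cq(miR-451a) rises with lysis, with
scores above 7 flagged as appreciable. Scores are computed on raw
(uncalibrated) values because they feed the calibration stage itself, and
are defined only when both proxies are acceptable in the sample; downstream
consumers fall back to the cohort median and flag the imputation.

## Calibration cascade

All calibration shifts are additive per-sample (or per-batch) constants, so
within-sample contrasts between assays are exactly preserved.

1. **Spike-in median alignment.** The exogenous calibration factor of a
   sample is the average of the mean duplicate cel-miR-39-3p Cq and the
   median Cq over the always-observed set; samples are shifted so every
   factor equals the cohort median factor. This removes the shared
   technical component (RNA-isolation and qPCR-efficiency differences).
2. **Sequence detrending.** Values centred per (donor, miRNA) are averaged
   per sample and smoothed over the processing sequence with a
   local-constant (Nadaraya–Watson) Gaussian kernel; the bandwidth
   minimizes leave-one-out squared error over an explicit log-spaced grid
   from half the minimum position gap to twice the sequence span. The grid
   search replaces derivative-based bandwidth optimization, which we found
   converges to degenerate flat-curve bandwidths on strongly trended
   sequences. The fitted curve value of a sample is subtracted from all its
   wells. A constant processing order skips the stage with a warning.
3. **Batch adjustment.** A REML mixed model on the kernel residuals with
   fixed effects for reaction status (censored vs acceptable), a centred
   quadratic in the hemolysis score (centred at the cohort median to
   decorrelate the linear and quadratic terms) and the baseline-distance
   technical flag, plus a random intercept per RNA-isolation batch. The
   batch BLUPs are subtracted and the result recentred to the stage input's
   global median (enforced exactly). A single batch or a zero batch-variance
   estimate degrades to a no-op.

Note an identifiability boundary we verified empirically: because the
calibration factor's endogenous half carries any batch effect present in
endogenous wells, and within-donor centring removes each donor's mean batch
exposure, batch effects that are (i) tracked by the spike-in or (ii) nested
within donors are removed *before* the mixed model and yield null BLUPs.
The BLUP machinery identifies batch artifacts that arise downstream of the
spike-in and vary within a donor's time course; the generator exposes that
scenario via `batch_mode="wave"` with `spikein_tracks_batch=False`.

## Normalization (censoring-aware multilevel interval regression)

Per miRNA, calibrated values are modelled on four per-sample covariates —
the miR-16-5p replicate mean, the median of set 1 (miR-24-3p, miR-484), the
median of the donor-specific subset of set 2 (members of
{miR-103a-3p, miR-126-3p, miR-191-5p, miR-30e-5p, miR-93-5p} acceptable in
every one of the donor's visits; subsets may differ by donor but must be
nonempty), and the hemolysis score — with a Gaussian random intercept per
donor. The likelihood uses exact densities for acceptable values, the
interval [calibrated Cq, 40] for censored values, and (40, ∞) for missing
values. The marginal likelihood integrates the random intercept with
adaptive Gauss–Hermite quadrature (15 nodes, centred per donor at a
closed-form Laplace approximation of the posterior mode — without the
adaptive centring the quadrature error exceeds the agreement tolerance we
require against a standard mixed model on censoring-free data) and is
maximized with L-BFGS-B on (β, log σ, log σ_b), followed by a
higher-order-difference polish; convergence is judged by the gradient norm.
Fixed-effect covariances come from the inverse observed information.

Normalized values: exact observations keep their observed calibrated value
minus the estimated covariate contribution (covariates centred at cohort
medians, so the hemolysis effect is adjusted to the median score); censored
observations are imputed by the truncated-normal conditional mean inside
their interval given the donor's posterior random effect; missing
observations by the conditional linear predictor — the model's most-likely
level for that donor and visit — with the (40, ∞) interval informing the
likelihood only. Imputing missing values at the truncated mean beyond 40
would manufacture residuals of 8+ cycles for any miRNA near the censoring
boundary and is inconsistent with the magnitude of test–retest SDs such
data actually show. SEs carry the adjustment uncertainty (x'Σ_β x) for
exact values and additionally the full residual variance for imputed ones,
so imputed SEs dominate exact ones uniformly.

Two behaviours worth knowing: (i) when reactions drop out by QC failure
near the censoring boundary rather than by exceeding Cq 40, the ">40"
missing-data rule is misspecified and the residual SD estimate inflates for
miRNAs whose mean sits in the dropout zone — a faithful property of the
method, visible in the model summaries; (ii) the three normalizer
covariates are strongly collinear within donors, so individual coefficients
are not interpretable — only the joint adjustment is.

## Stability indexing

Per miRNA, a weighted least-squares slope over the visit sequence is fit
per donor (weights 1/(σ̂_m² + SE²), combining the miRNA's residual variance
with the normalization SE), the slopes are averaged across donors, and the
variance of the average is the empirical between-donor slope variance over
the donor count (the cluster-robust sandwich for this estimator). Donors
with fewer than two usable visits are excluded with a warning.

Residuals about the grand line (donor offsets retained) are decomposed by
the unbalanced one-way ANOVA method of moments into a between-participant
variance (clipped at zero; the unclipped value is also reported, since
averaging clipped SDs across replicate studies carries an upward truncation
bias of roughly 10% at 22 donors) and the within-participant (test–retest)
variance; the total residual variance is their sum, so the decomposition
identity is exact. Both SDs are in Cq = log2-expression units; a miRNA is
*stable* when both are strictly below 1.0.

Drift converts the average Cq slope to percent change in expression per
month: drift% = 100·(2^(−slope·(365.25/12)/14) − 1) with a 14-day visit
interval (both configurable); a positive Cq slope is a negative expression
drift, and drift at ±s are exact reciprocals on the expression scale.

The dropout breakpoint scans every observed per-miRNA mean Cq as a
candidate threshold and compares pooled dropout proportions below vs above
with a two-sample z statistic on the pooled binomial SE (the statistic is a
choice; nothing published names one); the supremum wins, ties toward the
lower Cq, and uniform dropout yields an explicit no-break result. Note that
the *observed* acceptable-mean Cq of a miRNA near the dropout midpoint is
selection-shifted below its latent mean (only low draws are observed), so
the scan on observed means estimates the threshold of the observed-mean
scale, not the latent one.

## Metadata effects

Measurement bias outcomes are visit-level deviations of log2 expression
(= −Cq) from each donor's fitted trend — the across-donor average slope
anchored at the donor's mean, i.e. the stability model's trend; using each
donor's own noisy slope would absorb part of the visit-level effects being
estimated. Variance outcomes are donor-level log2 SDs of those deviations,
centred on the cohort mean, requiring at least three visits (zero SDs are
floored at 1e-3 and flagged).

Bias regressions use the five time-varying predictors (hemolysis score,
recent tobacco use, fasting, higher stress than the prior visit, ordinal
sleep-quality change); first-visit rows are dropped because change-type
predictors are undefined there. Variance regressions use the seven
donor-level predictors (average hemolysis, age per decade, average sleep
quality, average stress, fasting probability, sex, regular tobacco use).
The schemas are enforced; neither family mixes levels.

Each regression is an independent ridge fit: predictors standardized,
intercept unpenalized, penalty chosen by fivefold cross-validation over 50
log-spaced points on [1e-4, 1e4] scaled by the predictor count. Folds for
the visit-level regressions are grouped by donor so correlated visits never
straddle a fold boundary; donor-level regressions use seeded shuffled
folds. Weights are reported on the outcome scale per standardized
predictor; constant predictors get weight exactly 0. Effects at or beyond
log2(1.5) ≈ 0.585 are counted as large in either direction. Because
normalization already adjusts levels to the cohort-median hemolysis score,
the hemolysis *bias* weights downstream are attenuation residuals near
zero by construction; the hemolysis signal is quantified where it enters
(the normalization model and the generator's ground truth).

## Synthetic-study generator

The generator emulates the study design the pipeline assumes: 22 donors
sampled biweekly (4×5, 10×6, 8×7 visits = 136 draws; 15 female; ages
25–65), a 384-well card per draw (375 targets, miR-16-5p ×5,
cel-miR-39-3p ×2, ath-miR159a ×2), 134 measurable targets with baselines
uniform on [20, 36] cycles (non-measurable targets at 38–46, emulating the
never/rarely-amplifying majority), donor offsets SD 0.4, test–retest SDs
uniform on [0.2, 2.0], drift uniform on ±0.5%/month, a per-sample technical
shift SD 1.0 shared by the spike-in, residual isolation-batch effects SD
0.3, hemolysis scores ~1–11 with P(>7) ≈ 0.25 and per-miRNA sensitivities
(miR-451a at −1 cycle per score unit; a ~22% subset with moderate mixed
sensitivities), dropout probability logistic in the latent Cq (location 34,
scale 1.2 — set so that measurable-miRNA coverage and the qualitative
dropout break near Cq ≈ 30 match the study's description), censoring at 34
with maximum 40, two-decimal recording, and visit-varying metadata with
recent-tobacco level shifts (+0.8 log2 on 20 miRNAs) and donor-level noise
moderation (×1.5 for regular tobacco on 25 miRNAs, ×1.5 for males on 3).

Deliberate design choices: the named normalizer/proxy assays draw
test–retest SDs from U(0.25, 0.5) — normalizers are stable by selection,
and a 2-cycle-noise normalizer would contradict its role; the hemolysis
proxy pair shares its donor-level background (the difference score is used
precisely because it is donor-stable); isolation batches by default group
each donor's consecutive samples and are tracked by the spike-in (it is
added before isolation), which makes default batch adjustment a near no-op
— the `wave` mode exposes recoverable post-spike-in batch artifacts;
replicate studies can share one latent panel via `panel_seed`.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: no shared per-donor endogenous background
(so set-1 cross-donor normalization has nothing to remove by default;
`participant_background_sd` exposes it, but the between-donor ground truth
is then confounded), no amplification-efficiency or melt-curve structure,
no plate-position effects, no informative missingness beyond the latent-Cq
logistic, and metadata effects enter as clean additive/multiplicative
shifts rather than the correlated lifestyle patterns of a real cohort.

## Problem sizes used in the test suite

Unit tests run 8-donor, 15-assay studies; integration and property tests a
22-donor, 60/40-assay panel; the recovery suite 20 replicate 22-donor
studies over a fixed 75/55-assay panel (5 of them through the metadata
stage), with test–retest and between-participant SDs compared as
seed-averaged estimates (variances averaged before the square root for the
between component) over the consistently high-coverage non-normalizer
miRNAs; the variance-removal and decomposition checks use one full
default-scale study. These sizes are the package's own choices for a
thorough-but-quick default test run.
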