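# Methods

This note documents the models, conventions and numerical choices behind
`ctdnakit`, in the order the pipeline applies them.

## Assay post-processing

A tracked variant's allele fraction is estimated from consensus reads that
support the variant (NRv) or the reference (NRr): VAF = NRv/(NRv+NRr).
Equivocal reads are excluded from both numerator and denominator; when no
informative read exists the VAF is *missing*, deliberately distinct from a
measured zero. Calls are classified against a presumed-normal background
panel: **positive** requires at least `min_supporting_reads` (default 2)
variant reads *and* VAF above the panel maximum; **negative** requires VAF
below the panel's 0.95 quantile; anything else is **equivocal**. When a
degenerate panel makes both rules fire, positive wins — it is the stricter,
read-count-backed condition. Both pooled (variant-agnostic) and per-variant
panels are supported because background comparisons can reasonably be done
either way; per-variant values take precedence when present.

Sub-quantitation allele fractions are censored with LOD = 0.1% and
LOQ = 0.5% (assay defaults, configurable): AF ≥ LOQ is kept, LOD ≤ AF < LOQ
becomes LOQ/2, 0 < AF < LOD becomes LOQ/4. An AF of exactly zero stays zero:
censoring applies to *reported* mutations, and an absent variant carries no
allele fraction. Censoring on {0} ∪ [LOD, 1] is idempotent and
order-preserving.

Variants called positive in matched PBMCs are presumed germline/CHIP and
moved to an audit channel (`pbmc_positive=True`) rather than deleted, so
the subtraction is idempotent and auditable; burden summaries use only the
somatic channel. A gene blocklist (TET2, DNMT3A, CBL, PPM1D, CHEK2, JAK2,
ASXL1, SF3B1) is available for panels without matched normals.

**MTM.** Per-sample burden is summarized as mean tumor molecules per mL
plasma: the mean censored AF over positive somatic observations times the
cfDNA haploid genome equivalents per mL, using 3.3 pg per haploid genome
(configurable). No positive somatic observation gives MTM = 0. This
construction makes MTM and mean AF strongly rank-correlated, with cfDNA
concentration supplying the absolute scale.

## Feature derivation and landmark matrices

The metric catalog is configurable; the default covers the metric families
relevant to longitudinal ctDNA modeling — 11 per-visit level metrics
(mean/median/max/sum AF, MTM, log10(MTM+1), mutation and pathogenic-mutation
counts, cfDNA concentration, log10(cfDNA+1), detection indicator) and 15
change metrics (absolute, percent and log10-fold change of MTM, mean AF,
mutation count and cfDNA concentration; a clearance indicator for MTM < 1;
the time-weighted trapezoidal mean of MTM from baseline to date; the
on-treatment maximum MTM). Percent change is undefined (missing) at zero
baseline; absolute change is still computed. Percent-change metrics are
invariant to rescaling all AFs and concentrations by a common factor.

A landmark matrix at visit V contains level metrics for every visit up to V
and change metrics for every on-treatment visit up to V, with columns named
`VISIT:metric` / `VISIT_change:metric` so assembly is mechanical. A patient
is a row iff a sample-*collection* record exists for the landmark visit;
QC-failed samples keep their collection record but contribute missing cells
(the patient's earlier visits may still be informative). Clinical covariates
(age, sex, ECOG, smoking, metastatic-site count, PD-L1 status, baseline SLD,
and for C3D1 runs the week-6 SLD with its absolute and percent change) can
be appended.

Missing cells are imputed with the per-feature median of the *fit
population* only, and features are scaled by the fit population's
interquartile range. One quantile convention is used everywhere in the
package (panel quantiles, IQR, threshold percentiles): linear interpolation
between order statistics. Constant features pass through unscaled with a
warning. Imputation and scaling are refit inside every cross-validation
fold from that fold's training portion, so held-out patients never
influence them.

## Landmark survival modeling

**Rebaselining.** For a landmark analysis at collection day d, a patient is
at risk only if their event-or-censoring time is strictly greater than d;
time is re-measured from d. Events or censoring exactly at the landmark are
excluded (rebaselined time must be positive). Patients without a collection
record are excluded with reason "no collection". This removes immortal-time
bias: having survived to the landmark is constant among at-risk patients
and can carry no association.

**Elastic-net LOOCV.** Each leave-one-out fold IQR-scales and imputes from
its own training portion, then chooses the penalty strength by nested
cross-validation: k-fold (k = 5 by default) splitting repeated 10 times,
scoring each lambda on the path by the Verweij–Van Houwelingen
cross-validated partial-likelihood deviance
(−2·[ℓ(all) − ℓ(train)] at the inner-training solution), and averaging the
per-repeat deviance-minimizing lambdas. The mixing weight alpha = 0.5 gives
equal lasso and ridge weight. Path fitting is delegated to
scikit-survival's Coxnet (the glmnet coordinate-descent port); the
partial likelihood uses the Breslow tie convention, which coincides with
Efron and exact on the continuous survival times the generator produces.
Pooled held-out linear predictors reconstruct the training set and yield
the pooled c-index. Folds that fail to converge are flagged and contribute
a zero prediction. Fewer than 20 at-risk patients is refused.

**Feature importance.** Retention is the fraction of LOOCV folds selecting
the feature. The next-door gain is the increase in the fold's held-out
deviance when the feature is forced out and the model refit at the fold's
lambda, averaged over the folds that selected it; positive gain means the
model is worse without the feature. The published definition of the
worsening statistic was not available, so the deviance-based surrogate is
used and documented here. The top set is {retention ≥ 0.5 and gain > 0}.

**Final model.** An unpenalized Cox fit of the top features on the full
training set (plain coefficients transfer cleanly to external assays); on
degeneracy the fit is retried with a small ridge penalty and a warning.
Higher score = higher risk.

**Thresholds and calls.** The high-risk (mPD) threshold is the mean of the
two log-rank-optimal score splits computed separately within the week-6 SD
and PR subgroups; candidate cuts are the observed scores inside the
[10%, 90%] quantile range (avoiding degenerate tails), the criterion is the
log-rank chi-square, and ties break toward the smaller threshold. Subgroups
below 10 at-risk patients are refused (the pipeline orchestration falls
back to a pooled optimal split with a warning, for small synthetic runs).
The low-risk (mResp) threshold is the score percentile equal to the
fraction of at-risk training patients with durable survival — observed
(rebaselined) time of at least 36 months; patients censored earlier count
as not durable. By construction the mResp-labeled fraction matches the
durable fraction to within one order-statistic rank. Calls: score ≥ mPD
threshold → mPD; score < mResp threshold → mResp; the half-open band
between them → mSD (a score exactly at the mResp cut is mSD).

**Evaluation.** Harrell's c-index counts a directed pair (i, j) when
t_i < t_j and i had an event; tied predictions contribute 1/2. The standard
error comes from the leave-one-subject-out jackknife of the U-statistic
(cheap once pairwise contributions are tabulated, and consistent); the test
against 0.5 is the corresponding normal z-test, and two predictors are
compared by jackknifing the paired difference. Descriptive two-group
summaries use a univariable Cox model (lifelines, Efron ties) for the HR
with Wald CI, the two-sided log-rank test, and KM medians.

**Transfer.** An external cohort is scored with frozen coefficients and
thresholds after being imputed and IQR-scaled on its *own* population —
the convention for porting the score across assay technologies; the
features must be present by name.

## Trial simulation

Trials of 30 patients per arm are resampled with replacement (2,000
simulations by default). Endpoints are one-sided with small p favoring the
active arm: Fisher's exact test on mResp or RECIST-response counts (exact
hypergeometric tail, no mid-p), and the log-rank test on early PFS via the
signed statistic's normal tail. Combined ctDNA+radiographic endpoints use
the minimum of the two p-values. The go cutoff is the target-false-go
percentile (15% default, linear interpolation) of the endpoint's p-values
over null control-vs-control trials; Go means p strictly below the cutoff.
Combined endpoints are calibrated on the null distribution of the min-p
statistic itself — reusing a marginal cutoff would inflate the false-go
rate (both behaviors are demonstrated in the tests). Because the Fisher
p-value is discrete at n = 30/arm, the realized false-go rate can deviate
from the target by the mass of the p-value atom at the cutoff; at 2,000
simulations it lands within about two percentage points.

Under instantaneous enrollment, every patient's early PFS is
administratively censored at a common horizon — C3D1 day (42) plus the
14-day assay turnaround = 56 days by default (the package's reading of
"week-6 PFS"; configurable). Under ramp-up enrollment the calendar cutoff
is the last enrolled patient's C3D1 day plus turnaround, each patient's
follow-up is truncated at cutoff minus their own enrollment day, and
resampled patient sets must enroll within a 12-month window, enforced by
rejection sampling with 10,000 bounded retries (an error afterwards: the
constraint is infeasible for pools whose enrollment spread far exceeds the
window, since the range of 30 uniform draws concentrates near the pool
width).

## Synthetic cohort generator

The generator produces the study conditions the pipeline assumes, not a
forgery of any real dataset. Per patient: a treatment arm (control + two
active, 1:1:1); a latent week-6 response class (CR/PR, SD, PD with default
mix 0.35/0.55/0.10, shifted slightly toward CR/PR on active arms so the
treatment effect has a response-rate footprint); baseline covariates; and a
baseline tumor state in which log tumor size (SLD) and log mean allele
fraction share a latent factor (correlation ~0.4), with a median mean-AF of
1.4% and ~85% probability of carrying at least one somatic variant
(zero-truncated Poisson count, mean 5, genes weighted toward
TP53/KRAS/STK11/EGFR).

On-treatment burden follows per-class per-visit multiplicative trajectories
whose cumulative products at C3D1 are ≈0.30 (CR/PR), ≈0.61 (SD) and ≈1.54
(PD) — i.e. mean changes of −70%, −39% and +54% — with lognormal visit
noise (sd 0.35) shared with the week-6 SLD change so ctDNA and radiographic
kinetics correlate. RECIST categories derive from the SLD change (CR/PR ≤
−30%, PD ≥ +20%, else SD). The observation layer draws variant-supporting
reads binomially at 5,400× consensus depth, which produces natural
limit-of-detection behavior; CHIP variants (64% carrier rate, 1 + Poisson(0.8)
variants, AF median 1.3% that does not respond to therapy) appear in plasma
at every visit and in the matched PBMC calls.

Survival is generated by inverse transform from an exponential baseline
hazard (closed form, easy parameter-recovery oracles) with a linear
predictor on log10(baseline MTM + 1), response class and arm, centered at
the cohort-typical burden and class mix so the configured baseline medians
are realized cohort-level medians: defaults give ≈19-month median OS and
≈8-month median PFS, the scale of first-line metastatic NSCLC chemo-ICI
trials. Administrative follow-up is 1,250 days (~41 months) — long enough
that 3-year durable survival measured from the C3D1 landmark is defined —
plus light independent exponential censoring. Samples after a PFS event
are never collected (progression-driven dropout, making sample availability
monotone non-increasing across visits), and 3% of collected samples fail
assay QC, keeping their collection record without variant data to exercise
the imputation path.

What the generator does **not** emulate: sequencing reads or genomic
coordinates (variant ids are opaque tokens with a gene label), mutational
signatures, panel design, clonal evolution (no new variants on treatment),
post-study therapy effects on OS, or inter-visit correlation structure
beyond the shared class trajectory. Passing tests therefore demonstrate
that the *procedures* behave correctly under a proportional-hazards world
with class-driven kinetics — not that any specific real-data effect size is
reproduced.

## Problem sizes and numerical notes

The test suite exercises the LOOCV machinery at n = 150–200 with 10–20
features and the trial simulator at 2,000 simulations — sizes at which the
Monte-Carlo properties under test (false-go calibration within ±2 points,
null c-index behavior, parameter-recovery majorities across 10 seeds) are
stable while the suite stays desk-scale. Random state is threaded
explicitly: cohort generation, nested-CV splitting and trial resampling
each derive independent generators from the configured seed, and LOOCV
itself is deterministic given the data and config.

One honest caveat, measured rather than assumed: under a pure null
(features independent of survival) the pooled LOOCV c-index of this
procedure is *not* tightly concentrated at 0.5. Averaging per-repeat
deviance-minimizing lambdas pushes the fold's lambda below the zero-model
point whenever any repeat's noisy CV curve dips, and a fold then selects
the strongest spurious feature precisely when the held-out patient's data
opposed that feature's spurious correlation — making nonzero held-out
predictions systematically anti-concordant (values near 0.42 occur), while
stably-selected spurious features push the pooled c toward their own
optimism (~0.55). An independent R glmnet implementation of the same
procedure reproduces this spread, so it is a property of the statistic, not
of this implementation.
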