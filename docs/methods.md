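# Methods

This note documents the models, numerical choices and synthetic-data design
behind `frailmeth`, and what the test suite does and does not establish
about real data.

## Data model and transforms

A cohort is a probes × samples beta matrix (values in [0, 1], NaN for
missing), a probe manifest (chromosome, 1-based position, CpG-island and
TSS relation, linked genes, optional non-CpG / SNP flags) and a sample
sheet (one row per mouse × timepoint: sex, cohort, treatment, age in
months, the 31-item frailty index, survival).  All statistics run on
M-values, M = log2(β/(1−β)), with betas clipped at ε = 1e-6 so boundary
values stay finite; the inverse transform is exact on the interior.
Missing betas are excluded pairwise throughout — never imputed — with two
deliberate exceptions noted below (PCA, clock features).

The frailty index enters models as its natural logarithm.  `log_fi` errors
on FI ≤ 0 by default; the analysis layers pass a configurable floor of
half the smallest positive grid value (0.5/62 ≈ 0.008) because an aged
cohort can, rarely, produce an all-zero item sheet.

Probe filtering applies, in order: manifest flags (non-CpG, SNP), a
detection rule (non-missing fraction ≥ 0.95 by default — the threshold is
configurable because published descriptions of this filter are often
ambiguous), and a near-zero-variance rule (beta variance > 1e-10).  The
filter report accounts for every probe exactly once; filtering is
idempotent.

## EWAS with repeated measures

Design matrices use group-means coding in the sex-inclusive mode (sexF,
sexM, sexF:logFI, sexM:logFI, no reference level), and intercept + logFI
in the stratified modes.  Male samples at the last timepoint are excluded
from the sex-inclusive analysis by default: male survivorship at the
oldest age is sparse and unbalances the design.

Repeated measures are handled with a single **consensus intra-mouse
correlation**: per probe, OLS residuals of the design are decomposed by a
one-way moment estimator (between/within-mouse mean squares, with the
unbalanced-size correction n₀); per-probe correlations are Fisher-z
transformed, combined by a 10% trimmed mean, and transformed back.  GLS
then whitens each mouse block under compound symmetry — for an observed
block of size k the inverse square root acts as
(y − ȳ)/√(1−ρ) + ȳ/√(1+(k−1)ρ) — with block sizes recomputed per probe
from its missingness pattern, so all probes are fitted simultaneously by
batched linear algebra.  With ρ = 0 this reduces exactly to OLS.

Residual variances are shrunk by an empirical-Bayes scaled
inverse-chi-square prior fitted by method of moments on log s²
(digamma/trigamma inversion, Newton iteration for the trigamma inverse).
When the log-variances show no excess dispersion the prior df is capped at
1e7 and the prior scale is the plain mean of s².  Probes with zero residual
variance are excluded from the moment fit and assigned the prior scale.
The stratified statistic is the moderated t on the logFI slope; the
sex-inclusive statistic is the moderated F jointly on the two sex-specific
logFI slopes (the DMR stage weights probes by |t| or √F accordingly).
DMPs are probes with BH-adjusted p < 0.05.

PCA variance partitioning centers each probe and imputes the (≈1%)
missing entries at the probe mean — a full matrix is required for the SVD;
this is the one place missingness is imputed, and only for a descriptive
summary.  The smallest PC set explaining 95% of variance is retained; each
factor's share is the PC-variance-weighted sum of single-factor R².

## DMR calling

Squared statistics are smoothed per chromosome with a Gaussian kernel of
SD λ/C (λ = 1000 bp, C = 2), truncated at 3 SD — the truncation keeps the
brute-force oracle cheap and matches the kernel's effective support.
Under the null each squared statistic is treated as χ²₁ and the smoothed
value, a normalized positive combination Y = Σwᵢχ²₁ with Σwᵢ = 1, is
approximated by Satterthwaite moment matching: Y ≈ a·χ²_ν with a = Σw²,
ν = 1/Σw².  This ignores the correlation of neighboring statistics and is
therefore approximate — its role is ranking and chaining, with the
region-level Stouffer combination as the reported evidence.  Significant
probes (BH-adjusted smoothed p < 0.05) chain while consecutive gaps stay
within λ; chains need ≥ 5 CpGs and a Stouffer-combined p < 0.05.
P-values exactly 0 or 1 are clipped at 1e-15 before the normal-quantile
transform (with a warning).

The rdrop filter is single-pass by default (each CpG's pairwise-complete
Pearson correlation with the row-sum of the other members, computed once;
CpGs below 0.4 removed), with a recursive mode behind a flag.  Zero-
variance CpGs get rdrop 0.  The ≥ 5 CpG rule is enforced both at region
formation and after rdrop — a deliberately conservative double application.

## Region classification (AIFI / ADFI)

Member-CpG M-values in long format are fitted by an in-house REML mixed
model with **three** crossed random intercepts: mouse (repeated measures),
CpG (baseline differences among members) and sample.  The sample term is a
considered addition to the mouse + CpG structure: member CpGs are
co-methylated, so within one sample they share a regional deviation and
are not independent replicates of the sample-level covariates; without the
sample term the Wald tests were strongly anti-conservative in simulation
(whole classes of planted regions flipped label on unlucky cohort draws).
`fit_dmr_lmm(sample_effect=False)` restores the two-term model.

The REML criterion profiles out the residual scale and optimizes the
variance ratios on the log scale by Nelder–Mead; each evaluation uses the
Woodbury identity on precomputed cross-products, with the largest factor
Schur-eliminated (its ZtZ block is diagonal for one-hot factors), so a
region fit costs tens of milliseconds.  On single-random-effect reductions
the fitter agrees with statsmodels MixedLM to ~1e-4 relative.

Three fixed-effect models are fitted per region: logFI + age (AIFI focal
coefficient: logFI), age alone (ADFI), and logFI alone (the reported
frailty effect size and direction).  Wald tests use the standard normal
reference (a Satterthwaite-df option was considered and left out; at the
study's sizes the difference is small, and the null-calibration tests
confirm the type-I error).  BH adjustment is applied per model within each
subgroup over exactly the regions tested there; α = 0.05.  Classes: aiDMR
(AIFI only), adDMR (ADFI only), dualDMR (both), none.

The sex-interaction scan fits sexM + logFI + sexM:logFI with the same
random structure; female/male slopes come from linear contrasts.  The
joint fiDMR set is the union of class ≠ none regions across subgroups with
provenance both_sexes / female_only / male_only / inclusive_only, plus a
merged-interval view (≥ 1 bp overlap).

## Future-frailty associations

Consecutive-assessment pairs (current, future) and triples (past, current,
future) define the outcome frames; an all-ordered-pairs mode exists behind
a flag.  The DMR enters as its median member-CpG M-value per sample —
frailty is one value per sample, so long-format CpG rows would
pseudo-replicate the outcome.  Models: outcome ~ predictor + age + sex
(+ ΔAge₁ with ΔM, + ΔAge₂ with future outcomes — these gap terms are
dropped automatically when assessments are perfectly regular and the gaps
constant), with a mouse random intercept whenever a mouse contributes more
than one row.  A parallel fit with a centered predictor × age term
supplies the age-interaction p; regions with BH-adjusted interaction
p < α are flagged and excluded from the significant set.  A sensitivity
refit adds baseline logFI.  Concordance labels each discovery-significant
(region, analysis) pair consistent / flipped / not_replicated against the
validation cohort and summarizes sign agreement by discovery-|coef|
quartile.

## X-inactivation decision tree

Per chrX probe, per-sex beta means and min–max ranges (missing values
dropped; a symmetric-quantile option exists) feed a fixed decision order:
escape (both means < 0.15 and ranges overlapping or difference < 0.10),
inactivated (difference > 0.10, ranges disjoint), variable escape
(difference > 0.10, ranges overlapping), otherwise unclassified.  All
inequalities are strict; boundary ties fall through to unclassified.  The
0.15 threshold is on the beta (0–1) scale.

## Variability and entropy

Breusch–Pagan: per probe, an OLS mean model M ~ logFI (+ sex in a mixed
cohort, + per-mouse fixed intercepts when samples repeat — without them
within-mouse residual clustering inflates the test) yields residuals whose
squares are regressed on logFI; the statistic is n·R² against χ²₁, BH
across probes, VMPs at adjusted p < 0.1.  Exactly constant squared
residuals are guarded against float dust and give statistic 0.  The SNR of
a probe is var(fitted frailty component)/var(residual) from the same mean
model; deterministic > 10, stochastic < 1, strict inequalities, zero
residual variance → SNR ∞ (flagged).  The random-slope decomposition uses
statsmodels MixedLM with correlated random intercept + slope per mouse,
falling back to independent effects (flagged) on non-convergence.
Shannon entropy is the per-site mean binary entropy in log base 2, so it
lies in [0, 1]; 0·log 0 = 0 and missing betas are skipped.

## Clocks

Features are the member CpGs of the top-100 regions by |logFI-only
coefficient| (ties: adjusted p, then region id).  Sex (and age for EFC1)
are unpenalized: they are partialled out of the response and the CpG
features — exact for convex penalties — and their coefficients recovered
afterwards.  Missing feature values are imputed at training means (stored
on the model for prediction).  The elastic net (mixing 0.5) runs along a
100-alpha CV path with mouse-grouped 5-fold splits and the 1-SE rule,
followed by one adaptive refinement: survivors are reweighted by
(1/|coef|)² and refitted on the same path.  The refinement exists because
prediction-optimal penalties over-select — on planted-signal data the
single-pass fit kept 2–3× more false than true features, while the
adaptive step recovers the support cleanly; `adaptive=False` disables it.
Evaluation reports R² and adjusted R² (p = nonzero CpGs + covariates)
against an age + sex baseline refitted on the same split, pooled and per
sex; lifespan variance regresses time-to-death (uncensored mice only) on
the clock prediction, the conventional FI and age + sex.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the study design: 20 F / 25 M untreated discovery
and 20 F / 24 M treated validation mice, up to five assessments at ages
21/24/27/30/33 months (the true assessment ages are not public;
these are placeholders on a realistic aging window), ~4,400 probes with
200 planted regions by default.  Latent frailty is
η = a + b·age + u_mouse + q(t), with q a per-mouse Gaussian random walk —
the *age-independent* driver the AIFI analysis is supposed to find; each
of 31 items thresholds η + noise into 0/0.5/1, so FI lies exactly on the
k/62 grid.  The intercept and age slope are calibrated so mean FI rises
from ≈0.15 at 21 months to ≈0.35 at 33 months.  Mortality is a
discrete-time logistic hazard in current FI (intercept −3, slope 4),
truncating records and reproducing survivorship bias.

Methylation is generated on the M scale: bimodal baselines (betas
concentrated near 0 and 1), a per-probe sex offset, planted regional
effects (age slope 0.10 M/month for ad/dual, frailty-driver coupling
2.0 M per unit q for ai/dual — dual regions share one sign, since opposite
signs cancel in the marginal logFI association and would make the planted
class undetectable by construction), sex-gated and opposite-sign classes,
region-shared sample noise and per-(mouse, region) intercepts that create
the co-methylation the rdrop filter measures, male heteroscedastic (VMP)
probes with residual SD ∝ (1 + 3·FI), chrX dosage patterns per XCI class
(a few variably escaping probes additionally coupled to q in females),
chrY probes missing in females, and 1% missingness completely at random.

Not emulated: genomic sequence context, array chemistry artifacts, batch
effects, cell-composition shifts, informative missingness, any treatment
effect of NMN (the validation cohort differs only by label and sampling),
island/TSS annotation correlated with effects (context enrichment is null
by construction), or a global drift of betas toward 0.5 with frailty
(entropy trends are tested with targeted constructions, not the default
cohort).  Passing tests therefore demonstrate that the statistical
machinery recovers what it is designed to recover under honest noise,
repeated measures and survivorship — not that real cohorts will show
effects of this size or cleanliness.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: ~4,400–5,000
probes, 45–89 mice, 20 replicates for null calibration, 100 replicates for
CI coverage, 200 planted regions for recovery — sizes at which every
stochastic check is stable yet a full run finishes in minutes.  Nelder–
Mead tolerances on the REML variance ratios are 5e-3 (log scale); kernel
support 3 SD; Stouffer clipping 1e-15; beta clipping 1e-6; the prior-df
cap 1e7; the elastic-net path has 100 alphas with max_iter 20,000/50,000.
Fixed seeds make the generator byte-identical and the clock fits
bit-reproducible; the pipeline fans one seed out to per-stage substreams
by hashing the stage name.

## Known limitations

* The Satterthwaite smoothing p-values ignore inter-probe correlation of
  the statistics; they are a ranking device, calibrated only through the
  downstream BH + Stouffer + mixed-model gauntlet (which the null tests
  check end to end).
* The Wald tests use a normal reference; with fewer than ~20 mice they
  would need a df correction that is not implemented.
* The consensus-correlation estimator assumes a single shared ρ across
  probes; probe-specific correlation structure is absorbed, not modeled.
* chrY probes are removed by the default detection filter (missing in
  females); no chrY analysis is provided.
* `validate_concordance` matches regions by id, so discovery and
  validation must use one region definition (as in the pipeline).
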