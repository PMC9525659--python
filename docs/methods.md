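# Methods

## Scope and model

The package analyses the mediation chain prenatal exposure → cord-blood DNA
methylation → infant neurodevelopment with linear models throughout. Two
exposures are built in: a smoking gradient measured by urinary cotinine
(continuous ng/ml; bands <10 non-smoker, 10–499 passive, ≥500 active) and a
binary alcohol-use indicator. Outcomes are Bayley-III composite scores
(cognitive, language, motor, adaptive behavior, socioemotional) at 6 and 24
months. Every model adjusts for maternal age, HIV status, depression,
psychological distress, SES (4-level ordinal, treated as linear), gestational
age, child sex, cord-blood cell-type proportions, five genetic principal
components, and the co-exposure. Because the seven cell-type proportions sum
to one, the default adjustment set drops one of them (nRBC) to keep designs
full rank.

Assumptions inherited from the linear structural model: no exposure–mediator
interaction (hence TE = ACME + ADE exactly and PM = ACME/TE at the
point-estimate level), sequential ignorability given the covariates, and
complete-case analysis per model (sample sizes therefore differ by outcome
domain and timepoint).

## Total effects and the HDMA gate

Adjusted total effects are OLS fits per exposure × domain; mediation
screening runs only for pairs with an "indication of a total effect",
operationalised as two-sided p < `gate_p` (default 0.05) with a manual
`gate_include` override for borderline pairs a user judges worth screening.

## Robust per-probe scans

The E→M model regresses each probe's beta value on the exposure and
covariates; the M→Y model regresses the outcome on the probe, the exposure
(required for a valid decomposition) and covariates. Both use Huber
M-estimation: tuning constant 1.345, scale re-estimated each iteration as
median(|r|)/0.6745, IRLS to a parameter tolerance of 1e-8, at most 50
iterations; standard errors use the H1 form with the small-sample correction
factor κ = 1 + (k/n)·var(ψ′)/mean(ψ′)², and p-values come from t(n−k).
Because the pipeline fits tens of thousands of such regressions, the IRLS is
batched over probes (chunked BLAS normal equations); a test verifies it
matches single-fit `statsmodels` RLM (HuberT, MAD scale, H1 covariance) to
numerical precision. Probes with zero-variance methylation or non-convergent
IRLS are flagged and excluded downstream.

## DACT

The null of no mediation is composite: (a=0, b≠0), (a≠0, b=0), (a=0, b=0).
Case proportions are estimated from the scan's z-score vectors with Efron's
empirical null: a normal N(δ, σ²) is fitted by truncated-normal maximum
likelihood to the central 80% of z-scores (10th–90th percentiles) and
π₀ = min(1, central empirical mass / fitted null mass on that window). The
central-50% (interquartile) window was rejected during development: its
truncated likelihood is nearly flat in σ, so σ̂ ranged 0.84–2.1 on pure
N(0,1) null scores; the central-80% window recovers σ within ±0.04 on the
same inputs and estimates π₀ ≈ 0.92 when 10% of scores come from N(4,1).
With fewer than 200 tests the theoretical N(0,1) null with Storey's λ = 0.5
estimate of π₀ is used instead (logged).

With π_a and π_b the E-M and M-O null proportions, the case weights are
w₁′ = π_a(1−π_b), w₂′ = (1−π_a)π_b, w₃′ = π_aπ_b, normalised to sum to one,
and p_DACT = w₁·p_EM + w₂·p_MO + w₃·max(p_EM, p_MO)². Since max² ≤ max, the
DACT p-value never exceeds the larger component p-value. An optional
second-stage recalibration (inverse-normal transform of p_DACT, empirical
null refit, corrected tail probability) is available behind
`calibrate=True` / `--dact-calibrate` and is off by default.

Before DACT, probes are pre-filtered to p < 0.05 on both sides and, by
default, to a negative indirect sign (E-M × M-O product < 0), matching a
hypothesised harmful exposure; the null proportions are still estimated from
the full scan, and BH-FDR is applied within each exposure–outcome pair.

## HIMA-style screen

Sure independence screening keeps the d = ⌈n/log n⌉ probes with the largest
|M-Y effect| (ties: smaller p, then input order; the printed formula is
taken literally, with a `sis_mult` multiplier exposed for users who prefer a
multiple of d). The screened mediators then enter one joint outcome
regression with an unpenalised intercept/exposure/covariate block and the
minimax concave penalty (γ = 3) on the standardized mediator coefficients,
solved by coordinate descent over a 100-point log-spaced λ path spanning
three decades below λ_max with warm starts; the model is chosen by BIC
(n·log(RSS/n) + log(n)·df). Probes with nonzero coefficients get a
joint-significance p-value max(p_EM, p_MO) from the robust scan and BH
adjustment. No Python package in the environment provides MCP, so the
coordinate descent is implemented here; the univariate firm-threshold
operator is tested against brute-force minimisation and, in the unbiased
region |z| > γλ, the selected coefficient is tested to equal the joint OLS
slope.

## Causal mediation estimates

Both mediation models are fitted by OLS; `nsims` coefficient vectors are
drawn from each model's asymptotic multivariate normal (independent across
models, jointly within — so the b, c′ covariance is preserved). Per draw,
ACME = a·b, ADE = c′, TE = ACME + ADE. Point estimates use the fitted
coefficients; intervals are 2.5/97.5 Monte-Carlo percentiles; p-values are
two-sided tail probabilities floored at 2/nsims. PM draws are ACME/TE
restricted to draws whose TE sign matches the point estimate — PM is not
identified when TE changes sign, so the fraction discarded is reported and
flagged above 10%. The point-estimate ratio (rather than the mean of
per-draw ratios) defines PM because it preserves the PM = ACME/TE identity
that reported tables rely on. A nonparametric bootstrap engine (resample
rows, refit both models, percentile intervals) is provided for users who
prefer resampling; the quasi-Bayesian engine is the default because it is
deterministic given a seed and orders of magnitude cheaper per probe.
A probe is reported a significant mediator when ACME p < 0.05 and TE
p < 0.05; 6-month mediators are re-tested against the 24-month outcome with
the same criterion.

## Synthetic cohorts

The generator reproduces the structure the pipeline assumes, with defaults
chosen as the study conditions the package is designed around: n = 262
samples; active-smoker prevalence 0.2977 (the ≥500 ng/ml cut is applied to a
two-component log-normal cotinine mixture whose class is drawn first, so the
prevalence is exact in expectation); alcohol prevalence 0.1718; outcomes
centred near 100 with SD ≈ 15 and domain/timepoint location shifts; 6-month
outcomes observed for 112/262 and 24-month for 184/262 samples.

Probes lie on one synthetic chromosome: CMR blocks first (within-block gap
200 bp, between-feature gap 10 kb, so a 1 kb max-gap rule separates blocks
unambiguously), then singleton probes. Block betas are logit-normal with an
equicorrelated latent structure at the configured within-CMR correlation
(default 0.7). Planted effect probes are singletons: their beta is the
logit-normal baseline plus an additive a·E shift on the beta scale, clipped
to [0.001, 0.999], so two-stage least squares recovers the planted slopes
without transformation bias. Planted defaults (a = 0.05 beta units per
exposure unit, b = −30 score units per beta unit, direct effect −6) give
per-mediator indirect effects of −1.5 points on the target (motor) domain —
the scale of published single-CpG mediation estimates for a binary prenatal
exposure — and keep outcomes on the Bayley scale with 20 mediators planted.
The 24-month planted effect defaults to zero, mirroring designs where
6-month findings do not replicate at 24 months. E-M-only probes (a ≠ 0,
b = 0) exercise the distinction between exposure-associated and mediating
CpGs. Simulated external EWAS weights give effect sizes proportional to the
planted a (±15% noise) with p ≈ 10⁻³⁰ at signal probes and Uniform(0,1)
p-values elsewhere.

What the generator does not emulate: array technical artifacts (batch,
probe chemistry, detection failures), genetic control of methylation
(mQTL), non-Gaussian outcome tails, informative missingness, and
correlation between planted mediators beyond their shared exposure. Passing
tests therefore demonstrate correctness of the statistical machinery under
the assumed data-generating process, not robustness to those real-data
features.

## Numerical choices and degenerate inputs

- Threshold grid for MRS: 5×10⁻¹ … 5×10⁻³⁰ in decade steps; strict
  inequality p < threshold; a threshold passing zero probes yields a flagged
  all-zero score, and a fully degenerate grid raises. Prediction accuracy is
  the squared Pearson correlation between the raw score and the exposure.
- CMR detection: greedy chaining with max_gap = 1000 bp and min_cor = 0.3
  (Pearson, adjacent probes); singleton chains discarded; clumping ties on p
  broken by genomic position (leftmost).
- MRS mediation is attempted only when the best r² ≥ 0.05 (a score that
  cannot predict its exposure cannot carry an interpretable indirect
  effect).
- BH adjustment delegates to the standard step-up implementation and is
  tested against a hand enumeration over all 4-element grid vectors.
- Rank-deficient designs raise with the collinear columns named; constant
  mediators are flagged, not fitted; TE = 0 makes PM undefined (NaN).
- All randomness flows through numpy Generators seeded explicitly;
  pipeline sub-seeds are derived deterministically from the run seed, so
  identical configurations reproduce byte-identical reports.

## Problem sizes in the test and acceptance suites

Test-size calibration uses 10,000 probes at n = 200; ACME recovery uses 300
replicates at n = 2000 with a planted indirect effect of −2.0; the
end-to-end recovery uses 20 cohorts of 2000 probes at n = 500 with 20
planted mediators; MRS behavior uses n = 262 with 1000 probes over 20
seeds. These sizes make the whole suite run in a few minutes on one CPU
while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- DACT with the pre-filter is anti-conservative in principle (the filter
  conditions on small p-values); the pipeline's observed FDR stays below
  0.15 in the planted-signal regime tested, but the final ACME/TE
  significance filter is what controls it.
- The empirical-null fit assumes the central z-scores are dominated by
  nulls; with dense signal (>30–40% non-null) π₀ and hence the DACT weights
  degrade.
- PM intervals are meaningless when TE is near zero; the sign-restriction
  flag should be checked before quoting them.
- Huber scans protect against outlying samples, not against confounding;
  the covariate set is the user's responsibility.
- The CMR step is a simplified greedy chain, not a resampling-calibrated
  region finder; it is meant to de-duplicate correlated probes before
  clumping, not to define biologically interpretable regions.
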