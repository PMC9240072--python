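# Methods

This note documents the statistical procedures, the synthetic-data model
and the numerical choices behind `grimkit`, in the order the pipeline runs
them.

## Data model and aggregation

Raw observations are per-frame ordinal scores: five facial action units
(FAUs) in {0, 1, 2}, with −1 marking a frame rejected for that criterion.
The analysis unit is the *video* (animal × week × day × intervention
phase). Per video and FAU, rejected frames are excluded and the remaining
scores aggregated; the default `scaled_sum` mode is (mean per accepted
frame) × 8, the nominal frame count, placing every FAU on a 0–16 scale that
is comparable across videos regardless of how many frames were rejected.
`mean` (0–2) and `sum` (0–16 but biased low under rejection) are retained
as options. The published intercepts, intervention shifts and severity
thresholds (3 and 6) of the reference study only make sense on a
multi-frame total scale, which motivates the `scaled_sum` default; the raw
deposition needed to adjudicate the exact historical choice is not shipped
with the package, so the mode remains configurable.

The *average picture score* — the response of the penalized regression —
is the mean, over frames with **all five** FAUs accepted, of the per-frame
sum of the five scores (range 0–10). Frames missing any FAU are excluded
rather than imputed; videos without a single complete frame have an
undefined response and are dropped from that regression (with a warning).

Duplicate (animal, week, day, phase) rows in raw input are treated as
frames of the same video and pooled. Videos in which every frame is
rejected for some FAU are dropped and counted.

## Synthetic study generator

The generator emulates a two-arm repeated-injection design: 12 + 12
animals (Oil vehicle vs CCl₄), week 0 un-injected baseline (3 videos per
animal), weeks 1–4 with 3 injection days × pre/post videos, 8 frames per
video. Whole videos go missing with probability 0.23, reproducing the
reference bookkeeping of ~498 retained records out of 648 planned.

**Latent pain.** Each video carries
`L = u_a + t·1[CCl4, week ≥ 1] + (i + b·1[CCl4])·1[post] + w·week + ε_v`
with animal intercepts `u_a ~ N(0, 0.22²)`, substance effect `t = 0.2`,
injection effect `i = 0.14` (both arms — the needle itself hurts), a
CCl₄-specific increment `b = 0.26`, no week trend by default (`w = 0`) and
video noise `ε_v ~ N(0, 0.25²)`. Units are the frame-level noise SD; with
the default thresholds one latent unit moves the per-video OT score by
roughly three points.

**Frame scores.** Per frame, FAU k draws a Gaussian latent
`X_k = s_k·L + Z_k` where `Z` follows an equicorrelated copula
(correlation 0.8) scaled by per-FAU noise factors, and is cut into
{0, 1, 2} at per-FAU baseline quantiles. Three deliberately asymmetric
ingredient sets plant the importance structure:

* *sensitivities* `s = (OT 1.0, EP 0.66, CB 0.46, NB 0.28, WC 0.05)` — the
  descending order every importance analysis should recover;
* *marginal widths* — OT uses the full 0–2 range at baseline
  (P₀ = 0.70, P₀₊₁ = 0.97) while the subtler criteria are scored 0 more
  often (WC: 0.86/0.992), mirroring how raters actually use the scale;
* *noise scales* (OT 0.68 … WC 1.1) — orbital tightening is the most
  reliably judged criterion in the inter-rater literature, whisker change
  the least.

**Rejection.** ~15% of frame scores are rejected, dominated by a
whole-frame quality component (probability 0.14 that a frame is unusable
for every FAU at once) plus small FAU-specific remainders (largest for
WC, marginal 0.174). The clustered structure matters: rejections that hit
FAUs independently would decouple the frame sets behind the average
picture score and the per-FAU predictors and systematically distort the
penalized regression toward high-rejection criteria — an artifact of frame
bookkeeping, not of pain signal. Real rejections ("image too blurry") are
frame-level events, which the common component models.

**Seeding.** One master seed; each animal consumes an independent
substream (`SeedSequence(seed, spawn_key=(animal,))`), so enlarging the
cohort leaves existing animals' data byte-identical.

**What the generator does and does not emulate.** It reproduces the design
geometry, record counts, rejection rate, mild-dominant baselines, an
intervention effect of ~2 OT units concentrated in the CCl₄ arm, ICCs of
0.2–0.3 and strongly positive inter-FAU correlations. It does *not*
reproduce: the reference study's absolute variance scale (ours is larger
by roughly 3×, so coefficients are comparable in sign and structure, not
magnitude); the combination of near-0.9 WC correlations with negligible WC
importance (a shared-factor copula cannot give a criterion high video-level
correlation while denying it pain loading at matched variances — our WC
pairs sit nearer 0.3–0.5); occasional severe-class baselines (~5–10% of
baseline records versus none in the reference counts); rater drift or
disagreement (single-rater model); and week trends (habituation), which
are off by default but available via `week_trend`. Passing tests therefore
demonstrate that the *methods* recover planted structure under realistic
noise — not that the generator is a digital twin of any real cohort.

## Coalition importance and Shapley attribution

The measure of a FAU subset is the tie-corrected Mann–Whitney effect size
of its composite score between pre- and post-injection videos (CCl₄ arm,
weeks 1–4 pooled, by default; a pooled-arms contrast is a configuration
switch). W is reported in the first-sample convention
(W = #{x>y} + ½·ties, equivalently rank-sum minus n₁(n₁+1)/2);
z uses the tie-corrected variance without continuity correction;
r = |z|/√N, which is comparable across unequal group sizes and
distributions. Cliff's δ = (#{x>y} − #{x<y})/(n₁n₂) is available as an
alternative measure. When both groups are identical constants the variance
vanishes and r is defined as 0.

All 31 non-empty subsets are scored and normalized to the maximum. Member
contributions are exact Shapley values of the sub-game restricted to the
subset (2⁵ coalitions — exact enumeration, no sampling), normalized to sum
to one within the subset; an all-zero sub-game falls back to equal shares.
Efficiency, symmetry, dummy-player and additivity are enforced by tests
against a brute-force average over all 120 player orderings.

## Penalized coefficient ranking

Per treatment arm, weeks 1–4 only (the intervention factor does not exist
at baseline; keeping week 0 would make the design rank-deficient). The
design holds 15 columns — five FAU scores, five FAU × week (week numeric
1–4; a categorical option exists since "time" could be coded either way)
and five FAU × post terms — each standardized to zero mean and unit sample
SD so coefficient magnitudes are comparable. The λ grid is 100
log-spaced points from λ_max (the smallest penalty that zeroes all
coefficients) down by 10⁻⁴. Ten-fold cross-validation (seeded, shuffled
folds) scores the path per fold; λ_1SE is the largest penalty whose mean
CV MSE is within one standard error of the minimum, and coefficients are
refit on all data at λ_1SE. The coordinate-descent solver is
scikit-learn's; the module owns the design, scaling, folds and the 1-SE
rule. Three-way FAU × week × intervention terms are deliberately not
included.

## Mixed-effects models

Orbital tightening is the response throughout. Model I (all data,
between-treatments) has fixed effects treatment × intervention + day +
day × treatment + day × intervention (references Oil / pre / day 1) and
random intercepts for animal, week and day-within-week. Models II/III
(within CCl₄ / Oil, weeks 1–4, reference week 1) have fixed week ×
intervention and a random animal intercept. Estimation is REML
(statsmodels `MixedLM`; optimizer chain Powell → L-BFGS, 5000 iterations);
fits at the τ = 0 boundary are returned flagged, not errored. Variance
components are reported in response units with percentage shares and
ICC = Στ/(Στ+σ²).

Degrees of freedom use a Satterthwaite approximation computed in-package:
for each coefficient, df = 2·Var(β̂)² / (gᵀA g), where g is the numeric
gradient of Var(β̂) with respect to the free variance parameters
(central differences, step max(10⁻⁴, 10⁻³·θ)) and A the inverse negative
numeric Hessian of the profiled REML log-likelihood. Components at the
boundary are held fixed; an unusable Hessian falls back to the normal
approximation. On Model-II-type data the resulting df agree with
lmerTest's Satterthwaite implementation to ~0.01 df (a live lme4/lmerTest
cross-check is part of the test suite). Satterthwaite approximates, but is
not identical to, the Kenward–Roger correction; point estimates are
unaffected either way.

## Severity statistics

Per-video OT scores discretize as mild < 3 ≤ moderate ≤ 6 < severe (both
cut points inclusive to moderate). Count tables are treatment ×
intervention × class; arm-level class distributions are tested with the
Pearson χ² of independence *without* continuity correction — the choice is
validated by exact reproduction of the reference study's printed
statistics (37.15 and 10.579 on df 4) from its count table.

Post-hocs compare each severity-class *pair* across the three intervention
phases (2 × 3 Pearson χ²), with Benjamini–Hochberg FDR adjustment by
default (Holm and Bonferroni available). This scheme reproduces the
reference study's Oil adjusted p-values to the printed precision
(0.044 / 0.285 / 0.627), which is what pins it down among the several
schemes the literature's post-hoc packages offer. Sub-tables with expected
counts below 5 are flagged and accompanied by an exact conditional
(Fisher–Freeman–Halton, full enumeration for 2 × C) p-value as a
sensitivity column; the exact p does not replace the χ² p in the
adjustment, because doing so would break the exact reproduction above.

Group contrasts (e.g. baseline week 0 vs week-1 post) reuse the
Mann–Whitney machinery, two-sided, with the selector definitions recorded
for provenance. Central tendencies are bootstrap medians: 10,000 resamples
with replacement at original size, percentile 2.5/97.5 CI, point estimate
the median of the bootstrap distribution (which guarantees
ci_low ≤ median ≤ ci_high even for heavily tied ordinal data). Inter-FAU
correlations are Pearson by default (Spearman optional) on the aggregated
scores pooled over time and intervention; constant columns yield undefined
(NaN) entries rather than an error. Shapiro–Wilk with Q-Q quantile pairs
(valid for 3 ≤ n ≤ 5000) backs the decision to summarize by medians.

## Pipeline and reproducibility

`run_all` executes ingest → aggregate → coalition ranking → LASSO (both
arms) → Models I–III → severity in order, logs one line per stage with
input hash and wall time, and emits a versioned JSON report plus CSV
tables. All stochastic stages (generator, CV folds, bootstrap) take
explicit seeds recorded in the report; identical configuration gives a
byte-identical report. A failed stage aborts with the stage name.

## Test and script problem sizes

The suite validates methods at sizes chosen for tight feedback: 100 random
coalition games against the permutation oracle; 100 seeded Mann–Whitney
draws against O(n²) pair counting; 100 REML parameter-recovery replicates
(12 clusters × 24 observations; β and τ within 2 Monte-Carlo SE — the
residual variance carries a real ~2% finite-sample REML bias at 12
clusters, matched by lme4 to six decimals, and is checked at 5%); 500
bootstrap coverage simulations (n = 30, 2000 resamples) requiring 90–99%
coverage; 100 full synthetic studies for planted-order recovery (Kendall
τ ≥ 0.8 in ≥ 90%) and 200 for the OT-first regression (≥ 95%).
`scripts/acceptance.py` runs one full study plus the desk reproduction and
defaults to the full 10,000 bootstrap resamples.

## Known limitations

* Kenward–Roger df are not implemented; Satterthwaite is the closest
  portable approximation and can be anti-conservative in very small
  samples.
* The exact-test enumeration is implemented for 2 × C tables only (the
  post-hoc shape); general R × C exact tests are out of scope.
* λ_1SE depends on the fold assignment; with unseeded folds (as in
  interactive R sessions) it is not a stable quantity, which is why the
  package seeds folds and reports the seed.
* The generator's effect calibration targets the *shape* of the reference
  results (ordering, ICC range, mild-dominant baselines), not their
  absolute variance scale; see the generator section.
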