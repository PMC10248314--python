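# Methods

## The index model

Each battery component is an embedded validity indicator with a failure
direction (`low_fails` or `high_fails`) and three cut values
`(c1, c2, c3)` ordered liberal → ultra-conservative. Recoding is induced
purely by the cuts with half-open comparisons, inclusive of the printed
threshold on the failing side:

* `low_fails`: level 0 if `raw > c1`; 1 if `c2 < raw ≤ c1`; 2 if
  `c3 < raw ≤ c2`; 3 if `raw ≤ c3`;
* `high_fails`: mirrored with `≥`.

This makes the recoding a total, monotone partition of the valid score
range: published tables sometimes print the interior levels as closed
bands on the instrument's score grid (e.g. figure-copy bands
"25.5–29.0" / "22.5–25.0" on a 0.5-point grid), which leaves off-grid
values such as 25.25 formally unassigned. The cut-value representation
coincides with the printed bands on the grid and classifies off-grid
inputs on the liberal side of the nearest cutoff (a score of 25.25
*passed* the 25.0 cutoff, hence level 1). Boundary conventions follow
the printed "≤ / ≥" notation; ties with a cutoff always fail, never
randomized.

The index total is the unweighted sum of levels; the bands
(`pass_max`, `borderline_max`) are configuration, not constants,
because alternative fail cutoffs (e.g. ≥ 3) are a live topic in this
literature — the packaged default is the standard (≤1 / 2–3 / ≥4) for
k = 5. A battery whose Fail band is unattainable (`borderline_max + 1 >
3k`) is rejected at validation time. Borderline rows keep their label
and are excluded only where a dichotomy is required (the
`joint_outcome` grouping, sensitivity/specificity of the Fail cutoff).

Missing component scores raise by default, naming row and component; an
explicit `complete_case` policy drops incomplete examinees and logs the
count. No prorating is offered: partial batteries change the meaning of
the sum, so a shorter battery should be declared as its own config.

## Criterion machinery

Free-standing criterion PVT outcomes (WMT, MSVT, NV-MSVT) are consumed
as given Pass/Fail labels — their internal scoring rules are
proprietary and not reimplemented. The G-3 composite labels zero
failures Pass, exactly one failure Indeterminate (excluded from
dichotomous grouping — a lone failure is insufficient evidence), and
≥ 2 failures Fail; a configurable dichotomy (≥1 / ≥2 / 3) supports
sensitivity analyses. The WMT three-way outcome is the one criterion
rule published in full and is computed from the IR/DR/CNS subscale
percentages: Fail if any subscale < 85.0%, Borderline if any equals
85.0% (none below), Pass otherwise; equality is compared after rounding
inputs to one decimal, matching how the percentages are reported.

TOMM-1 failure defaults to ≤ 42. Published tables are inconsistent
here (one note uses ≤ 42, another ≤ 43); the package defaults to 42
and leaves the cutoff a parameter of the generic sweep machinery rather
than resolving the discrepancy.

## Diagnostics

All rates use the standard formulas; `occ = (TP + TN)/N` and `br_fail =
(TP + FP)/N`. Computation is at full float precision; a single
formatting layer (`erdodi.formatting`) applies display rounding with
round-half-away-from-zero (rates one decimal as percents, metrics 2–3
decimals), so reports and full-precision values can be compared
independently.

AUC is the Mann–Whitney statistic normalized by `n₁n₂` (ties credited
0.5), oriented by the fail direction, with the Hanley–McNeil normal
approximation for the SE and a CI truncated to [0, 1]. The SE method
is a documented choice: it is closed-form, deterministic, and matches
common statistics-package defaults at these sample sizes; tests verify
the AUC against an exhaustive pairwise oracle and the trapezoidal ROC
area, not the CI width.

Cohen's *d* defaults to the average-variance denominator
`√((s₁² + s₂²)/2)`; that unweighted convention reproduces the published
between-band contrasts (e.g. 284.5/20.4 vs 237.8/40.0 → d = 1.47),
whereas df-weighted pooling does not (1.87 on the same inputs). The
pooled-by-df variant is available behind `pooled_df=True` with explicit
group sizes. Φ² = χ²/N with the Pearson statistic (no continuity
correction).

One reconstruction caveat: published OCC cells for composite-vs-
composite comparisons cannot always be rebuilt from the printed
sensitivity/specificity and group sizes under the stated OCC formula —
the denominator composition (whether indeterminate criterion cases are
included) is ambiguous in the source tables. The implementation applies
the stated formula over criterion-included cases and makes no attempt
to match those cells.

## Synthetic cohorts

The generator is invented for testability: the source cohort is
archival and undeposited, and no generative model is described for it.
It emulates a mixed clinical/forensic referral stream of n = 452 with
20% non-credible responders. Per examinee and component, deficit
severity is `z = √ρ·f + √(1−ρ)·e` (shared factor f, ρ = 0.3), scores
are `μ ± σ·m·z ± δ·σ·noncredible` with δ = 2.0 SD toward the failure
direction and an SD multiplier m = 1.5 for non-credible responders
(inflated within-group variability is a replicated marker of invalid
performance), then snapped to the instrument grid and clipped.
Criterion PVT failures are Bernoulli given the latent state with
per-test (sensitivity, specificity) defaults of (.80, .90), (.72, .95),
(.70, .96) — chosen so that, at 20% prevalence, criterion base rates of
failure land near the 17–24% range characteristic of such cohorts.
Credible-state score locations (e.g. Coding ACSS 9.5 ± 3, figure copy
32 ± 3) sit in the mildly-impaired clinical range of each instrument.

What passing tests show — and don't. The generator reproduces the
*structure* the model assumes (latent state, correlated deficits,
imperfect criteria), so recovery tests validate the pipeline's
arithmetic and monotonicity, not clinical accuracy: real cohorts have
demographic confounds, non-Gaussian floors, instrument-specific
dependence and referral-dependent prevalence that the copula model does
not emulate. Headline accuracy figures from the source cohort are
therefore not test targets.

The no-signal condition used for the null-AUC check sets both the mean
shift and the SD multiplier to neutral (δ = 0, m = 1) — with m > 1 the
inflated spread alone is a detectable signal, which is a property of
the model, not a bug.

## Problem sizes and numerics

Exhaustive enumeration of level-vector space is guarded at k ≤ 10
(4¹⁰ ≈ 10⁶ vectors). Simulation-based tests use n = 5000 for null and
distributional checks, n = 2000–3000 for the effect-size grid with
common random numbers (same seed across grid points), chosen to keep
Monte-Carlo error well inside the asserted tolerances (±0.03 on a null
AUC at n = 5000). The AUC pairwise oracle is exercised on all cohorts
of ≤ 8 cases, where exhaustion is exact. All randomness flows through
`numpy.random.default_rng(seed)`; identical parameters and seed
reproduce cohorts bit-for-bit.

## Known limitations

* Criterion PVT internal scoring is out of scope by design; garbage
  labels in, garbage criterion analyses out.
* The WMT Borderline rule is sensitive to the one-decimal rounding
  convention of its inputs; percentages reported at other precisions
  should be rounded upstream.
* `complete_case` drops rows silently apart from a log line; coverage
  differences between indices (as occur in archival tables) are the
  caller's bookkeeping.
* The simulator's correlation structure is a single shared factor;
  real EVI batteries show richer (e.g. modality-specific) dependence.
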