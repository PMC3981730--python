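# Methods

This note documents the models, defaults and numerical choices behind
`fvgame`, and what the synthetic-study tests do and do not establish.

## The measurement model

Consumption is school-level, never individual-level: the waste measure
`(P − U − W − dressing) / (S · N)` yields the between-student average
proportion of one serving consumed. Every subtraction in the numerator can
only *under*-estimate consumption, so a negative numerator is treated as a
data error (weighing inconsistency) rather than clamped to zero. Serving
weight `S` is a single per-day per-variety value even though real servings
varied slightly by grade band; treat it as the attendance-weighted mean
serving weight. Unit conversions use a per-variety grams-per-quarter-cup
table: the salad (14.25 g) and canned-green-bean (38.25 g) entries are
measured values; all other entries are synthetic fixture values flagged as
such in `data/serving_weights.yaml`, to be replaced with measured weights
for real analyses. Dressing is subtracted whenever a nonzero dressing
weight is recorded, regardless of variety.

## The goal engine

The percentile schedule's operational definition — the school met or beat
the goal on 4 of the last 10 target-day values — pins the goal to the 7th
ascending order statistic of the 10-value window. A nearest-rank "60th
percentile" (6th order statistic) leaves 5 of 10 values at-or-above and
fails that criterion, so `four_of_ten` is the default and `nearest_rank`
is available for comparison. With ties the rule degrades gracefully: at
most 4 values exceed the goal strictly (an all-equal window returns the
common value).

Each category's first intervention goal is seeded with its 10 baseline
days (both foods were measured daily in baseline); thereafter only
*target-day* values re-enter that category's window, so non-target-day
consumption never moves the goal. Goal-met counts at equality. Currency
floors fractional percents (`floor(100 · max(0, c − g))`), with a 1e-9
tolerance so exact percentages survive binary floating point. Villain
captures are a pure function of cumulative goals met (thresholds 1, 8,
11); the 11th goal sets a terminal flag rather than raising, so ledgers
longer than the game are still replayable.

## SMA

The test statistic is the correlation (Pearson by default, i.e. the
point-biserial coefficient; Spearman optional) between the series and its
dummy-coded phase vector. Surrogates are stationary Gaussian AR(1) streams
of the same length; the p-value is `(1 + #extreme) / (1 + n_sims)` — the
add-one keeps a finite simulation from reporting p = 0. Two-tailed
comparison on |r| is the default; the one-tailed option exists for designs
where the direction is predicted a priori (as it is in an intervention
expected to increase consumption).

Autocorrelation is estimated on *phase-centered* residuals (each phase's
own mean removed) so that a genuine level shift does not masquerade as
autocorrelation. Centering two short segments costs real degrees of
freedom: to first order `E[r1] ≈ φ − k(1 + 3φ)/n` with `k` separately
centered segments. The default correction therefore *inverts* this
equation, `φ̂ = (r1 + k/n)/(1 − 3k/n)` with `k = 2`, clipped to ±0.99. At
the study's design size (5 baseline + 13 intervention points, φ = 0.3)
this recovers `E[φ̂] ≈ 0.31` and a type-I error of ~0.07 at α = .05,
whereas the classical one-step plug-in `r1 + (1 + 3 r1)/n` (kept as
`bias_correct_phi` and as `phi_correction="one_step"`) leaves
`E[φ̂] ≈ 0.18` and inflates the type-I error to ~0.10. The remaining mild
liberality is the unavoidable price of estimating φ from 18 points: runs
that underestimate φ are liberal, runs that overestimate it are
conservative, and the two do not cancel exactly. If a series equals an
exact phase step, the residuals are identically zero and white-noise
surrogates are used (the observed |r| = 1 is unbeatable regardless).

## CDC

Both criteria derive from the baseline alone: the mean line and the OLS
trend line fitted to baseline values against time indices `1..n_base`,
projected over `n_base+1..` (consecutive school days; calendar gaps
ignored), each raised by 0.5 baseline SDs (sample SD, n−1). Exceedance is
strict (`>`): boundary points do not count, because the question is whether
treatment points are *elevated above* the criteria. The count of treatment
points above both lines is referred to `Binomial(n_treatment, ½)` with
`p = P(X ≥ count)`. With 13 treatment days the significance threshold is
10 exceedances (`P(X ≥ 10) = 378/8192 ≈ .046`). A zero-variance baseline
degenerates both criteria to unshifted lines and is flagged.

## Trend, survey and median tests

The baseline-trend check reports a permutation test on the OLS slope
(primary; values shuffled over time indices, two-tailed on |slope|,
add-one estimator) and a Wald–Wolfowitz runs test about the median
(secondary). Both are reported because visual-analysis traditions use runs
tests for trend while the permutation test is the sharper tool for a
slope; a published p-value from either convention can be compared against
the matching output.

The Wilcoxon signed-rank test drops differences equal to the null location
(standard zero-handling), midranks ties, and computes the exact two-sided
p-value for n ≤ 25 from the full null distribution of `W+` via dynamic
programming over doubled ranks (doubling makes midranks integral); the
two-sided p doubles the smaller tail, capped at 1, matching
symmetric-distribution convention and scipy's exact method when there are
no ties. Beyond n = 25 a tie-corrected normal approximation is used.

Small-n Likert items (7 teachers) are judged by the distribution-free
median CI instead: the order-statistic pair `(x_(j), x_(n+1−j))` with the
largest `j` whose exact coverage `1 − 2·P(Bin(n,½) ≤ j−1)` still reaches
95% (at n = 7 that is the extreme pair, coverage ≈ 98.4%); an item is
positive when the lower bound exceeds the neutral rating 3. For n < 6 no
pair reaches 95% and the result is flagged not-computable rather than
raising. Parent items (n = 35) use the Wilcoxon test directly.

## The synthetic-study generator

Defaults mirror the study conditions: 10 baseline + 13 intervention days,
180 enrolled students with a 6% daily absence probability (absences drawn
binomially; the real rate was not reported), quarter-cup servings, AR(1)
daily noise (φ = 0.3, marginal SD 0.05 proportion units). The baseline
starts at 0.80 (fruit) / 0.52 (vegetable) proportion-of-serving and
declines 7% per day — fruit through the whole baseline, vegetable only
until day 5 — putting the comparison-baseline means near 0.11 and 0.09
cups, the levels the study reports. Target-day effects default to +0.35
(fruit) and +0.30 (vegetable) proportion units, sized so that target-day
consumption reaches roughly 0.20/0.17 cups. Effects are injected *only* on
intervention days and only into the targeted category; that is the ground
truth the recovery tests exploit.

Weights are synthesised backwards from the latent value: waste and
unserved fractions are drawn generously, rounded to the 100 g floor-scale
resolution, and the supply weight is then set so the waste measure
recovers the latent value; dressing (0.5 g per attending student on
dressed-vegetable days) uses the 1 g portion scale. Because unserved and
waste are rounded first, the recovered proportion is within
`50 g / (S · N)` of the latent value — the generator reports this
per-record tolerance in its ground truth, and tests assert recovery within
it. Near-zero latent values can round the numerator negative; the supply
is bumped one resolution step in that case to keep the record valid.

Surveys are latent-normal ratings centred at `3 + shift` (SD 1), rounded
and clipped to the 1–5 scale, with the study's respondent counts (7
teachers × 5 items, 35 parents × 10 items).

What the generator does *not* emulate: menu-driven variety effects on
consumption (weekday menus only rotate serving weights), carry-over or
satiation between days beyond AR(1) noise, non-target-day spillover of the
intervention (real interventions show some), individual students, and
measurement reactivity beyond the deterministic novelty decline. Passing
recovery tests therefore show the *pipeline* is correct under the stated
process, not that the process captures every feature of real cafeterias.

## Analysis-pipeline choices

The comparison baseline is the final 5 baseline days (novelty inflates the
early baseline; the vegetable series is stable over those days while fruit
was still declining — the baseline slope is reported alongside the SMA so
the caveat is visible, and no detrending is applied). The SMA series is
the trimmed baseline plus *all* 13 intervention days, ignoring target
labels; the CDC is run separately on target-day and non-target-day
subsets against the same trimmed baseline. A non-target subset with fewer
than 5 days is reported as skipped rather than tested (the CDC's validity
floor). Reports are plain dicts serialised with sorted keys so identical
inputs and seeds give byte-identical output.

One published figure is not reproducible from the published summary: the
fruit increase in cups works out to 64% from the rounded phase means
(0.11 → 0.18), while 66% was reported from the unrounded data; the
percent-increase routine reproduces the grams figures (84%, 28%) and the
vegetable cups figure (44%) exactly from the rounded means.

## Problem sizes in the validation suite

Calibration properties use the design geometry throughout: SMA type-I
error over 500 null AR(1) runs (φ = 0.3, 5 + 13 points, 5000 surrogates
each); SMA power at a +1.5 SD shift over 300 runs (directional test);
effect recovery over 50 synthetic studies scored per food (CDC fires on
target days, stays silent on non-target days; ~90% observed against a
floor of 80% — the shortfall is mostly studies where one food draws ≤ 4
target days, where the CDC cannot reach p < .05 even with every point
above both criteria); oracle equivalence on 200 random CDC instances,
1000 goal windows and 25 Wilcoxon samples. The CLI is a thin layer over
the same functions (`simulate`, `analyze`, `replay-game`, `report`).
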