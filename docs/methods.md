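# Methods

## The distribution test

Each sample is reduced to its empirical quantile function: the sorted
vector of its `n` feature values, viewed as the inverse CDF evaluated on
the shared grid `p_j = (j - 0.5)/n`. Squared Mallows (Wasserstein-2)
distances between two samples are approximated as the *mean* of squared
differences between their quantile vectors. Taking the mean rather than the
sum over the grid is a deliberate convention: any constant grid scaling
cancels in the F ratio, and the mean keeps SS values comparable across
feature counts.

With `F_ik^{-1}` the quantile function of sample `i` in group `k`,
`Fbar_k^{-1}` the elementwise mean within group `k` and `Fbar^{-1}` the
grand mean, the dispersion decomposes as

    sum_{k,i} ||F_ik - Fbar||^2  =  sum_k n_k ||Fbar_k - Fbar||^2
                                  + sum_{k,i} ||F_ik - Fbar_k||^2

and the statistic is `F = (SS_between/(K-1)) / (SS_within/(n_T-K))`.

**Grand-mean convention.** The decomposition above is an algebraic identity
only when the grand mean is the sample-size-weighted mean of the group
means (equivalently the plain mean over all `n_T` sample quantile
functions). We use that convention; for balanced designs it coincides with
the equal-group-weight average. The acceptance suite verifies the identity
to 1e-8 relative tolerance on random balanced and unbalanced designs.

**Median pre-step.** Samples are *always* median-centered before the
quantile computation, which makes the statistic invariant to per-sample
location shifts; the one-way ANOVA on the per-sample medians is reported
alongside as the location diagnostic rather than used as a gate. This keeps
the statistic deterministic (no data-dependent branch) and separates the
"distributions differ in location" question from the "distributions differ
in shape/spread" question.

**Degenerate cases.** `MS_within = 0` with `MS_between > 0` yields
`F = +inf` (which counts as ≥ any permuted value); both zero yields
`F = 0`. SS terms below `16 eps^2 * mean(S^2) * n_T` are treated as exact
zeros: averaging bit-identical columns (e.g. after quantile normalization)
perturbs the last bit and would otherwise turn a true 0/0 into a large
finite ratio of rounding noise.

**Permutation scheme.** Random mode draws `B` uniform permutations of the
label vector (group sizes preserved, duplicates allowed) and reports the
add-one p-value `(1 + #{F_b >= F_obs}) / (B + 1)`, which is a valid p-value
under exchangeability and can never be zero; ties count as exceedances.
Exhaustive mode enumerates every distinct label assignment (the identity
included) and reports the exact proportion. Each permutation re-evaluates
the full statistic for the permuted grouping; per-sample median centering
and sorting do not depend on the grouping, so the sorted centered matrix is
computed once — an algebraically exact shortcut, not an approximation. All
permutations are materialized from the seed before any parallel dispatch,
so results are identical for any worker count. Library default is
`B = 1000`; the CLI documents the `B = 100`, `alpha = 0.05` convention used
in array studies.

## Normalizers

*Quantile normalization* builds the reference as the rank-wise mean of the
per-sample sorted values and substitutes each value by the reference at its
within-sample rank. Tie handling is unspecified in the classic four-step
description; the default resolves ties by original row order through a
stable sort (deterministic, preserves the multiset invariant: every
normalized column is exactly the reference multiset), and `tie_mode=
"average"` instead assigns tied raw values the mean of the reference values
across their tied ranks, matching other common implementations. When all
sorted columns are already identical the shared column itself is used as
the reference, making repeated normalization a bit-exact fixed point.

*Median normalization* shifts every sample so its median equals the mean of
the original per-sample medians — a location-only adjustment that keeps the
data on their original scale.

*Spike-in scaling* subtracts, per sample, the log2-scale mean over the
spike-in control rows (equivalently divides by a geometric-mean factor on
the raw scale); output stays on the log2 scale and requires strictly
positive input.

*Guided normalization* runs the permutation test first: if `p >= alpha` the
matrix is quantile normalized, otherwise the values pass through untouched
(method `"none"`). Pass-through is literal — no silent median correction —
so users who still want a location adjustment compose `median_normalize`
explicitly.

## The simulator

The simulator emulates a two-group (default 2 x 5 samples) bead-array
methylation experiment.

**Truth.** Baseline methylation proportions come from a three-component
mixture of hypomethylated, hemimethylated and hypermethylated modes at
means (0.1, 0.5, 0.9) with weights (0.4, 0.2, 0.4) and Gaussian within-mode
jitter (sd 0.05), clipped to (0.02, 0.98) — the familiar bimodal-with-
shoulder shape of array beta values. A uniformly chosen `ceil(pi_dm *
n_cpgs)` subset is differentially methylated: group 2's proportion is
shifted by `|delta| ~ Uniform(0.2, 0.4)` with random sign (flipped toward
the interior if clipping would annihilate the effect, so every DM CpG keeps
a nonzero true delta).

**Observation.** Per sample, biological jitter (sd 0.01 on the proportion
scale) perturbs the group-mean proportion; methylated and unmethylated
target concentrations are `total_molecules * beta` and `total_molecules *
(1 - beta)` with `total_molecules = 10^4`. Each channel passes through a
Langmuir adsorption mean `baseline + saturation * c / (c + affinity)`
(defaults 500 + 10^4 * c / (c + 10^4), i.e. fluorescence in the thousands
with visible chemical saturation at high concentration), multiplied by a
per-sample per-channel log-normal scale factor (sd `sample_scale_sd`) and
by probe-level log-normal noise (sd 0.05). Observed betas are
`M / (M + U + 100)` with the platform-default offset 100.

Two placement choices matter. Technical variation is *per channel*: a
common gain applied to both channels would cancel almost completely in the
beta ratio, leaving nothing for normalization to remove; independent
methylated/unmethylated factors emulate dye and scanner differences and
produce the between-array distributional shifts that quantile normalization
exists to fix. Noise is multiplicative after the Langmuir mean, preserving
positivity. The Langmuir saturation attenuates observed effect sizes (a
true delta of 0.3 appears as roughly 0.2 on the observed-beta scale); this
attenuation is shared by every normalization strategy and is deliberately
left in, as it is a property of the platform, not of the analysis.

**Default technical-variation level.** `sample_scale_sd` sweeps
{0, 0.05, 0.1, 0.2}; the default is 0.05, fixed once by a design pilot:
at this level the test's rejection rate is ~alpha with 0–1% DM CpGs and
near 1 with 10% DM CpGs on 20,000-CpG arrays, i.e. the regime the method is
designed for (technical variation present but not so large that genuine
global signals drown). At 0.2 the within-group distributional variation
swamps a 10% DM signal at these sample sizes and the test (correctly,
given its null) stops rejecting; the sweep remains available in the config
for exploring exactly that trade-off.

**What the simulator does not model:** type I/type II probe chemistry,
probe-sequence affinity differences, batch-block structure, cell-type
mixtures, spatial artifacts, or gene expression. Passing tests therefore
show the statistical machinery behaves as designed under a clean generative
model, not that any particular real dataset satisfies the test's null.

## The evaluation harness

Differential methylation is called per CpG by a two-sample t-test on the
observed betas (pooled variance by default, Welch optional; zero-variance
rows get p = 1 and a flag instead of being dropped), adjusted by
Benjamini–Hochberg, selected at adjusted p <= 0.05 (or top-M for ROC
sweeps). Bias and MSE are computed over the truly DM CpGs only
(effect-recovery error of `mean(group2) - mean(group1)` against the true
delta); false-discovery counts, TPR and FPR use the full selection.
Effects are simulated on the proportion scale and tested on observed betas
directly — no M-value transform — matching common beta-value practice.

`run_study` crosses DM fractions with technical-variation levels, and for
every replicate runs both arms on the *same* simulated data: (i) always
quantile normalize, (ii) guided — so when the test accepts quantile
normalization the two arms are bit-identical and all contrast comes from
replicates where the test rejects. Scenario seeds are spawned from one
master generator, making the whole table reproducible from a single seed.

## Problem sizes

The shipped acceptance checks use 500 null replicates and 200 power
replicates of 5000-CpG, 2x5-sample arrays at B = 100 permutations, and 20
replicates per scenario of 20,000-CpG arrays for the normalization study —
sizes chosen so the full suite completes in about a minute on one CPU while
leaving Monte Carlo error well inside the asserted margins (e.g. the exact
binomial 99% interval for the calibration check). Larger runs are a matter
of changing the arguments.

## Known limitations

* The test is one-way by construction; no multi-factor designs.
* Quantile functions are compared on the shared order-statistic grid, which
  assumes equal feature counts per sample (always true for a matrix).
* The exhaustive mode is capped (default 10^5 assignments) — beyond that
  random permutations are the intended tool.
* With very few samples per group the permutation p-value is coarse
  (as in the worked example: three distinct splits, minimum p = 1/3).
* In the 1%-DM study scenario the guided arm occasionally (order of 1 in
  10-20 replicates) rejects because a replicate's realized technical
  between-group shift is genuinely large; the unnormalized data then carry
  correlated false discoveries, so the 20-replicate mean-FD comparison
  between the arms has heavy-tailed Monte Carlo variability. This is
  inherent to the method — it detects global changes of technical and
  biological origin alike and cannot tell them apart from the data — not a
  defect of the harness.
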