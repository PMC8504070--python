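# Methods

## Model and assumptions

The data are two non-negative feature-by-replicate matrices: `X` (d × m,
experimental condition) and `Y` (d × n, background condition). Feature `j`
is *uninteresting* when its expected measurement is the same under both
conditions; the analysis goal is to discover the complement set —
features with a higher experimental mean (enrichment) or a different mean
in either direction (differential) — with the false discovery rate
controlled at a user-chosen `q ∈ (0, 1)`.

FDR control rests on two assumptions and nothing else:

1. measurement errors are independent across features and replicates;
2. for every uninteresting feature, all `m + n` measurements are
   identically distributed.

No distributional family, variance model, or large-sample approximation
is involved; this is what makes the procedures robust at the replicate
numbers (1–3 per condition) typical of omics experiments.

## Contrast scores

Per-feature summaries of the two measurement vectors:

* minus: `t_minus(x, y) = x̄ − ȳ`;
* max: `max(x̄, ȳ) · sign(x̄ − ȳ)` (zero on ties);
* t-statistic: pooled two-sample t-type statistic (available as an
  alternative; empirically underpowered relative to the mean difference
  at small replicate numbers, because it spends information estimating
  within-condition variances and has a lighter right tail).

**Equal-replicate enrichment** applies a summary row-wise; the default is
the minus score. Under assumptions 1–2 a null feature's score is
symmetric about zero, so negative scores are one-per-feature negative
controls.

**Permutation construction** (unequal replicates, and all differential
analyses): the pooled `m + n` columns are re-split into every (or `h`
sampled) column subsets of size `m`. Two permutations assigning the same
column set to the pseudo-experimental group are equivalent, so there are
`C(m+n, m)` classes — halved to `C(2m, m)/2` for differential `m = n`,
where a split and its complement give the same absolute mean difference;
the canonical representative is the subset containing column 0.
Differential analysis therefore needs `m + n ≥ 3`; a 1vs1 design has a
single class and no negative controls. The per-class statistic is the
(absolute, for differential) pseudo mean difference. Sorting the `h + 1`
statistics `T(0) ≥ T(1) ≥ …`:

* minus score: `T(0) − T(1)` if the identity attains the maximum, else
  `T(1) − T(0)`;
* max score (default): `|T(0)|` if the identity is the strict unique
  maximum, `0` on a tie at the top, else `−|T(0)|`.

Tie handling is deliberately conservative: a top tie never produces
positive evidence (it contributes 0, which is excluded from the candidate
cutoff set). For the minus score a tie at the top yields `T(0) − T(1) = 0`
under the "identity attains the maximum" reading, which is equivalent.

## Thresholding

Candidate cutoffs are the non-zero absolute scores. The BC rule accepts
the smallest `t` with `(#{C_j ≤ −t} + 1) / max(#{C_j ≥ t}, 1) ≤ q`; the GZ
rule (for scores built from `h` permutation classes) replaces the
numerator with `(1/h)(1 + #{C_j ≤ −t})`. If no candidate qualifies, the
cutoff is `+∞` and the discovery set is empty. Features scoring exactly
at the cutoff are discoveries (`≥` semantics). The implementation scans
the sorted candidate set with vectorized rank counts (O(d log d)); an
independent O(d²) double-loop oracle lives in the test suite only.

Per-feature FDR estimates — the running minimum of the qualifying ratio
over candidates `t ≤ C_j`, clipped to [0, 1], set to 1 for non-positive
scores — are emitted alongside the discovery flag. Thresholding them at
any `q` reproduces that `q`'s discovery set exactly (a tested property),
which is also how the benchmark evaluates a whole `q` grid from one run.
They are contrast-score-based estimates, not p-values.

Numerical conventions: `±inf` scores are legal (an infinite positive
score is discovered at every finite cutoff); NaN scores are rejected at
validation. Zero-variance t-statistics return signed infinity with a
warning (ranking semantics preserved), and error only in the 0/0 case.

## Default route and configuration

`run_analysis` resolves `auto` settings deterministically from
`(mode, m, n)`: equal-replicate enrichment → minus score + BC; everything
else → permutation max score + GZ. Overrides are honored where defined;
BC is exposed only for the equal-replicate enrichment route. The number
of permutation classes defaults to exhaustive when `h_max ≤ 100` (the
plan is then seed-independent) and to 100 classes sampled uniformly
without replacement otherwise, reproducibly via a lexicographic
integer↔subset bijection and a user seed (default 1). The GZ guarantee
holds for any `h ≥ 1`; larger `h` mainly reduces the `1/h` additive
penalty and stabilizes the score ranking.

Features that are identically zero everywhere are retained: they score 0
and can never be discovered, but dropping them would silently change `d`
and the BC numerator, so any filtering is left to the caller — as is
between-sample normalization (e.g. TMM before count analyses). Input
matrices must be non-negative at load time; `run_analysis` accepts signed
data (Gaussian scales, log-ratios) via `require_nonnegative=False`, since
every score construction is well defined there and the mean-difference
paths are shift-invariant — only the enrichment reading of the *direct*
max score presumes a non-negative scale.

## Baselines

The comparator suite mirrors what bioinformatics pipelines actually do:

* *pooled* empirical p-values: a feature's experimental average ranked
  against all `d` background averages, add-one convention
  `(1 + count)/(d + 1)` to avoid zeros;
* *paired* tests: Gaussian — z-test when the noise sd is supplied as
  known (the fully specified simulation model), pooled-variance t-test
  otherwise; Poisson — exact conditional binomial test of the two count
  sums (two-sided p as twice the smaller tail, capped at 1);
* deliberate mis-implementations: `2as1` (one-sample test against the
  observed background mean treated as a constant) and `mis` (Poisson test
  applied to over-dispersed counts);
* thresholding by BH (statsmodels) or Storey's q-value with a single
  fixed `λ = 0.5` (a grid smoother adds nothing for benchmarking).

## Synthetic data and benchmark

`generate_dataset` draws d independent features. Background means: a
single `μ0` (5 for counts, 0 for Gaussian) under the homogeneous
scenario; i.i.d. Gamma(shape 2, scale 5) for counts or Uniform(0, 10) for
Gaussian under the heterogeneous scenario. A fraction `pi1` (default 0.1)
of features is interesting: experimental mean = fold `effect` (default 3)
times the background mean for enrichment, applied up or down with equal
probability for differential; in the mean-zero homogeneous Gaussian case
the effect acts as an additive shift of `effect · noise_sd`, since a fold
change of zero is vacuous. Replicates are i.i.d. Gaussian (sd 1), Poisson,
or negative binomial (size 2). Uninteresting features satisfy the
identical-distribution assumption exactly by construction — verified by a
rank test in the suite. Options: per-feature outliers (one random pooled
replicate multiplied by `outlier_factor` with probability `outlier_rate`)
and block dependence (Gaussian copula with a shared latent factor per
block of 50 features, preserving marginals).

What the generator does *not* emulate: batch effects, library-size
differences, feature-length biases, count-mean/variance trends, or any
semi-synthetic resampling of real data. Passing benchmarks here show the
procedures behave as the theory predicts under the stated assumptions;
they do not certify calibration on data violating assumption 2.

`run_benchmark` runs each method on `n_reps` datasets (replicate `r`
seeded `seed + r`), evaluates `FDP = V/max(R, 1)` and power against the
ground truth at each target `q`, and reports means with Monte-Carlo
standard errors; per-cell method failures are recorded as NaN rather than
aborting (e.g. there is no correctly-specified simple paired test for the
negative-binomial family).

Problem sizes used by the shipped checks: the acceptance script runs the
three headline settings at d = 10000 with 200 replicates; the test suite
asserts the same properties at d = 2000 (200 replicates) and the full
q-grid across six designs at 50 replicates — sizes at which the
Monte-Carlo standard error of the mean FDP is a few parts in a thousand,
ample for a bound check at q = 0.05.

## Known limitations and observations

* Under the default negative-binomial differential conditions
  (heterogeneous Gamma(2, 5) means, size 2, fold 3) the scores separate
  weakly: FDR control holds (it is assumption-driven, not
  parameter-driven) but power is low; stronger effects or lower
  dispersion are needed for informative power comparisons in that cell.
* The pooled empirical-p-value baseline is *valid* under this generator's
  heterogeneous backgrounds: when feature-level means are drawn i.i.d., a
  null feature's experimental average is exchangeable with the pooled
  background averages, so its empirical p-value is uniform regardless of
  heterogeneity. Pooled approaches fail in practice when the pooled null
  is fitted parametrically under a wrong homogeneity assumption or when
  the null features are not exchangeable with the pool — mechanisms
  outside this generator's scope.
* The `2as1` misformulation and outlier contamination of known-variance
  parametric tests reproduce their expected anti-conservative failures;
  the contrast-score method remains controlled in both (tested).
* Scores are plain mean differences: no covariate adjustment or
  batch-effect regression; multi-condition or continuous-condition
  designs are out of scope.
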