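# Methods

## Generative model

A game of the horizon task is parameterized by an ordered pair of aversive
probabilities (p₁, p₂) for its two arms, drawn uniformly per game from the
ordered pairs of {0.1, 0.3, 0.9} with distinct entries (6 pairs).  Distinct
pairs are the default because they pose an explore/exploit trade-off in
every game; a configuration switch (`TaskSpec.include_equal_pairs`) admits
equal pairs, whose outcome law is choice-independent and therefore carries
no information about exploration.

Each game runs 4 forced trials in the fixed allocation (arm 1, 2, 1, 2) —
two per arm, so the agent enters the free phase informed about both options
— followed by 6 free choices.  Outcomes are Bernoulli draws coded 0/−1.
Forced outcomes are drawn stochastically from the arm probabilities, not
scripted.  Action values start at Q₀ = (0, 0) and are updated after every
trial, forced trials included: the forced phase must inform later
exploitation, and the update after each observed outcome is what carries
that information.  The learning rate is fixed at α = 0.1 throughout (an
illustrative value; the machinery accepts any α ∈ [0, 1]).  Free choices
follow the softmax policy with temperature τ; all softmax evaluations use
max-shifted exponentials and are stable down to τ = 10⁻⁶.

Populations are normal in τ: participant values are drawn
Normal(μ_group, σ) with σ = 0.02 by default, truncated to the τ grid by
resampling (not clipping, which would put a point mass on the boundary; at
σ = 0.02 the truncation only matters for means within a few hundredths of
the grid floor).  In the two-group design loop the first group mean is
drawn uniformly on [0, 1 − Δμ_τ] and the second is offset by the true
difference Δμ_τ, so both means stay in [0, 1].

What the generator deliberately does *not* emulate: individual differences
in learning rate, directed (uncertainty-driven) exploration, within-game
drift in τ, more than two arms, continuous rewards, or trial-level
recording of choices.  Passing tests therefore validate the design
machinery under this idealized behavioural model, not the adequacy of the
model for any particular empirical population.

## Exact likelihood

The observed statistic per game is the free-phase aversive count
n_a ∈ {0,…,6}.  Its PMF given τ is computed exactly by expanding all
4^n_free (choice, outcome) paths, multiplying softmax choice and Bernoulli
outcome probabilities along each path with Q updated trial by trial, and
binning final path probabilities by aversive count.  Enumeration is carried
in linear probability space (path probabilities stay far above the float64
underflow threshold for τ ≥ 0.01) simultaneously for all grid values of τ;
rows are renormalized to remove accumulated round-off (they sum to 1 by
construction; the correction is ~10⁻¹⁵).

The likelihood of a dataset **conditions on the realized forced outcomes**
of each game: they are observed data, and the post-forced Q pair they
induce is the initial state of the free phase.  Under the 2+2 allocation
the post-forced Q pair takes only 16 values per arm pair, so at most
6 × 16 = 96 distinct PMF tables cover the whole default task; tables are
cached (`PmfBank`) keyed by (arm pair, Q pair rounded to 12 decimals) and
reused across every replicate, sweep cell and test.  An alternative
marginal likelihood (ignoring forced outcomes) would average these tables;
it is not implemented because the forced outcomes are always recorded in
this design.

Dataset and group log-likelihoods are element-wise sums over the τ grid.
The group model treats all participants in a group as sharing one τ — the
population σ of 0.02 is far below the likelihood's resolution at realistic
game counts, and an internal calibration check (SD of the difference
estimate vs the implied width of the 95% HPDI under the null) confirms the
approximation is benign at the default σ.

## Grid inference

All integrals are finite sums on bounded grids: τ ∈ [0.01, 3] in steps of
0.01 (300 points; the step resolves the population σ = 0.02), and
Δ = τ₂ − τ₁ on the same step over the achievable range
[−2.99, 2.99] ∩ [−3, 3], constructed from integers so that Δ = 0 is exactly
a grid point.  Priors are discrete uniform.

The difference density is the discrete cross-correlation of the two group
likelihoods, with the off-grid factor evaluated by linear interpolation of
the log-likelihood (smooth in log space; avoids grid-alignment artifacts)
and zero outside the τ grid.  Both the density and the Bayes factor are
computed after a common max-shift, so group likelihoods from ~10⁴ games
cannot underflow; a Bayes factor whose null density underflows to exact
zero while the numerator is positive returns an `inf` sentinel.

HPDIs admit grid points in order of decreasing probability until the target
mass is reached and report the spanning interval, with a `contiguous` flag;
on a multimodal posterior the spanning interval is wider than the
highest-density set, but the length metric stays a single number.  Evidence
categories use the Jeffreys thresholds (1/100, 1/30, 1/10, 1/3, 3, 10, 30,
100); a Bayes factor sitting exactly on a threshold is assigned the weaker
category, keeping evidence claims conservative.

## Design analysis loop

One replicate: draw means → draw participant τ values → simulate all games
→ group log-likelihoods → difference density → BF₁₀, posterior-mean
difference estimate, 95% HPDI.  Replicate seeds are spawned from
`SeedSequence(condition.seed)`, so any replicate can be recomputed in
isolation and execution order (or parallel scheduling) never changes
results; sweep cells likewise derive per-cell seeds from numeric keys only
(string hashes are process-dependent and are never used).

Summaries per condition: evidence-category frequencies; Pr(BF₁₀ > t) and
Pr(BF₁₀ < 1/t) for t ∈ {3, 10, 30, 100}; Type S rate (BF₁₀ < 1/3 with a
true nonzero difference — 1/10 is reported alongside, since "wrongly
supporting the null" is threshold-dependent); Type M exceedance (among
replicates with BF₁₀ > 10, the fraction whose signed relative
overestimation exceeds 10%; an absolute-value variant is available and the
metric is flagged undefined when no replicate reaches strong evidence or
the true difference is zero); MSEE of the difference estimate; and the mean
95% HPDI length.  The posterior-predictive integral behind the average
length criterion is approximated by the replicate datasets themselves —
they are draws from the same generative model, so no second simulation
layer is needed.  `alc_sample_size` returns the smallest candidate group
size whose average length meets the budget, and is nested in the budget by
construction.

The trend diagnostics (`descriptive_trends`) are ordinary least squares and
Spearman correlations over validation tables: estimates on truth with a
truth × n interaction, a cell-mean recovery fit (one averaged estimate per
(μ, n) cell — replicate noise otherwise bounds the attainable R²), and MSEE
on log-transformed group size and exponentially transformed truth, the
transform's scaling constant being fitted from the data by bounded
one-dimensional minimization.  These are descriptive checks outside the
Bayesian path; constant columns yield an `undefined-correlation` flag
rather than an error.

## Problem sizes and tolerances

Default test and validation sizes were chosen to keep a full run on one CPU
in minutes: the validation grid uses μ ∈ {0.1,…,0.9}, n ∈ {10, 30, 50} at
150 games and 50 repetitions per cell; headline design conditions run 250
to 750 replicates (Monte-Carlo SE on a rate near 50% is then 1.8–3.2
percentage points, which is the dominant uncertainty in any reported rate).
PMF rows are normalized within 10⁻¹⁰; posterior constructions are checked
to the same tolerance; the difference density matches an O(G²) double-sum
oracle to 10⁻⁸ relative error.

## Known limitations

* The shared-τ group likelihood understates between-participant
  heterogeneity when σ is large relative to the likelihood width; the
  default σ = 0.02 is safely below that regime but the approximation should
  be revisited for heterogeneous populations.
* Path enumeration scales as 4^n_free and is practical up to ~10 free
  trials; longer horizons need a different likelihood strategy.
* The count statistic n_a discards trial-level choice information; designs
  that record individual choices could reach the same evidence with fewer
  games.
* Bayes factors here test a point null on a bounded uniform prior; rates
  such as Pr(BF₁₀ > 10) shift with the prior's support, which is part of
  the analysis specification, not a nuisance constant.
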