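# Methods

## Record model and time axis

A usable record is a fight between exactly two identified animals of one
pen with a clear initiator, receiver, winner and loser, lasting more than
1 s.  Rows that do not meet this (unidentified participants, melees
involving more than two animals, winners that are not participants,
timestamps outside the observation schedule) are routed to a reject report
with reason codes rather than silently dropped, so the filtering step is
auditable.

Observation follows a daytime schedule with an overnight gap (no recording
18:00–07:00; mixing at 12:00).  Analysis time is the *cumulative observed
hour*: piecewise-linear in wall-clock time, 0 at mixing, flat across gaps.
It is always derived from the timestamp — a value in an input file is never
trusted.  Windows are half-open `[start, end)`, so a fight logged exactly
at 18:00 belongs to no window and is rejected; whether such boundary fights
should instead be truncated is unknowable from a point timestamp, and
exclusion is the conservative choice.  The presets are 28 observed hours
for weaned piglets (6 + 11 + 11) and 17 for fattening pigs and gilts
(6 + 11); arbitrary daily windows can be configured.

## Dyad categories

Per pen, all `n(n−1)/2` unordered pairs are tallied.  Categories: *unknown*
(no fights), *one-way* (one animal won everything), *tied* (equal nonzero
counts), *two-way* (wins in both directions, one animal ahead).  Two-way
and tied are defined disjointly so the four categories partition the dyads
and their percentages sum to 100 exactly; a nested reading (tied ⊂ two-way)
would double-count.  Fight counts over dyads conserve the record count.

## Dyad-individual limits

The sign-test statistic of a dyad is `x = wins_lo`, the win count of the
member with fewer wins; `p = P(X ≤ x)` under `Binomial(n_fights, ½)` is
evaluated with exact integer arithmetic (`Σ C(n,k) / 2ⁿ` as a rational),
avoiding any floating-point tail summation.  The critical value
`x_max(n, α)` is the smallest x whose exact CDF reaches α, so significance
(`x < x_max`, strictly) is equivalent to `p < α`.  `x_max = 0` for
`n_fights < 5` at α = 0.05: such dyads can never be significant, and at
five fights only 5–0 passes.

One statistical subtlety is documented rather than hidden: because the
tested animal is chosen *after* seeing the outcome (the one with fewer
wins), the realised type-I rate at a fixed `n_fights` is
`2·P(X ≤ x_max−1)`, which exceeds α at some sizes (0.0625 at n = 5, 0.0703
at n = 8) and undershoots at others.  Averaged over realistic mixtures of
dyad sizes the rate is slightly below α (≈ 0.049 under the simulator's
null), which the acceptance suite verifies by simulation.  Users comparing
against two-sided conventions from the older literature should note the
one-sided rule has strictly higher limits.

## Pen-individual limits

The pen's sample is the win difference `diff = wins_hi − wins_lo` of every
*interacting* dyad (`n_fights ≥ 1`).  Never-interacting dyads are excluded
by default: their zeros reflect group size and avoidance, not fight
outcomes, and would drag the limit toward 0 in large pens.  A flag
(`include_zero_diff_dyads`) includes them for sensitivity analyses.

The limit is an endpoint of the distribution-free confidence interval for
the median difference.  Order-statistic intervals `(X₍d₎, X₍n−d+1₎)` only
achieve a discrete set of coverages `1 − 2·P(X ≤ d−1)`; the requested level
(default 0.95) is met by linear interpolation between the innermost
interval covering at least the level and the next interval inside it
(Hettmansperger–Sheather interpolation, as in the sign-test routines of the
R ecosystem).  When even the sample range cannot achieve the level (fewer
than six values at 0.95), the endpoints clamp to the sample minimum and
maximum.  Degenerate samples (all equal) give a zero-width interval.

The default limit is the *upper* endpoint of the two-sided interval; a
one-sided lower confidence bound is available
(`pen_limit_mode="one_sided_lower"`).  The upper endpoint was chosen
because it yields a finite, pen-adaptive threshold with the intended
qualitative behaviour: low-fighting pens get low limits, and the pen rule
retains more dyads than the rigid per-dyad rule exactly where the latter
starves.  A dyad is significant iff `diff > limit`, strictly, mirroring the
strict `x < x_max` of the dyad rule.  A pen with no interacting dyads has
no limit and no significant dyads.

## Data sets and bookkeeping

`ALL` holds every clear-outcome record; `PEN` and `DYAD` the records of
dyads significant under the respective rule (subsets of `ALL` by
construction).  A pen is counted in a data set only when at least one of
its interactions is retained, and the data set's animal count is the full
roster of those pens — an animal whose own fights were all pruned still
belongs to a retained pen (its DI is then undefined).

## Dominance index

`DI = (wins·P_won − defeats·P_lost) / ((wins + defeats)·(n − 1))` with
`P_won` = distinct pen mates the focal animal beat at least once and
`P_lost` = distinct pen mates that beat it at least once.  (Some published
prose swaps the two P labels; only this reading satisfies the stated range,
giving +1 exactly when `defeats = 0` and `P_won = n − 1`.)  `n` is the
original group size even for the pruned data sets — the index normalises by
the social environment the animal lived in, not by how many of its fights
survived a filter.  DI is undefined (reported separately, never binned or
zero-filled) when `wins + defeats = 0`; inconsistent count combinations
(e.g. `P_won > 0` with `wins = 0`) raise.

Expanding windows grow in 1-observed-hour steps from mixing to the full
period; counts are taken over `observed_hour < end`, so windows nest and
per-animal counts are non-decreasing in window length.  DI histograms use
bin width 0.1 over [−1, 1] by default, with the final bin adjusted when the
width does not divide the range.

## Comparisons

Spearman rank correlations (average-rank tie handling) between data-set DIs
are computed per expanding window, pooling animals across pens; animals
with an undefined DI in either data set of a pair are excluded pairwise,
and windows with fewer than 3 common animals are omitted.  Kruskal–Wallis
uses the tie-corrected H with a chi-square reference (the all-identical
degenerate case returns H = 0, p = 1).  Dunn's post-hoc z statistics on
mean ranks use the matching tie correction — for two groups z² equals the
tie-corrected H exactly, which the tests verify — with Bonferroni
adjustment by default (holm and none available).  Category contrasts
between data sets treat pens as the experimental units, since the
percentages are per-pen quantities.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
pig behaviour per se.  Per pen: latent strengths are standard normal; each
dyad is structurally avoided with probability `p_avoid`; otherwise its
fight count is negative binomial with mean `base_rate` and dispersion 3
(overdispersion reproduces the large across-pen spread of fight counts seen
in real mixing data; Poisson would not); fight times are drawn from an
exponentially decaying intensity (`rate_decay` 0.1 per observed hour —
fighting declines after mixing) mapped through the schedule, so the
overnight gap holds no records; winners follow
`P(i beats j) = logistic(k·(sᵢ − sⱼ))` with steepness `k` (0 = exact null,
default 2 = strong hierarchy); the winner initiates with probability 0.8.
One RNG substream per pen makes pen *i* identical whatever the pen count.

Presets target the field picture of the three mixing events:

| preset         | pen size | base_rate | p_avoid | T (h) | fights/animal |
|----------------|----------|-----------|---------|-------|---------------|
| weaned_piglet  | 9        | 1.9       | 0.20    | 28    | ≈ 12          |
| fattening_pig  | 21       | 0.66      | 0.55    | 17    | ≈ 6           |
| gilt           | 21       | 0.66      | 0.60    | 17    | ≈ 5           |

What the simulator does **not** model: winner/loser and bystander effects
(strengths are static), ritualised displays and threats, body-weight or
familiarity covariates, observer misses, or within-day circadian structure
beyond the monotone decay.  Passing tests therefore show the pipeline's
statistical machinery is correct under the stated generative assumptions —
not that real pens satisfy those assumptions.

## Problem sizes and determinism

Every stochastic test and script is seeded.  The statistical suites use:
1000 simulated pens for the partition/conservation invariants; ~400 pens
(≥ 10⁴ testable dyads) for the null calibration of the dyad rule, asserted
at `α + 3·MC standard errors`; 100 replicates of 5 nine-animal pens
(`k = 2`, `base_rate = 3`, `p_avoid = 0.1`) for latent-strength recovery,
requiring Spearman(DI, strength) > 0.7 in ≥ 90 replicates; and 100
replicates of 12 gilt-preset pens for the pen-vs-dyad rule ordering.  The
whole suite runs in well under a minute on one core.

## Known limitations

* The pen-limit endpoint convention (upper endpoint of a two-sided 95 %
  interval) is one defensible choice among several; results for sparse pens
  are sensitive to it, which is why it is a run parameter, logged with
  every run.
* The post-hoc-minimum construction of the dyad test means per-size type-I
  rates straddle α (see above); the rule is implemented as defined in the
  field, not "corrected".
* Spearman series pool animals across pens; DIs are pen-relative
  quantities, so the pooled correlation mixes within- and between-pen
  ordering.
* With very few interacting dyads the median CI clamps to the sample range
  and the pen limit equals the largest observed difference, so no dyad can
  be significant (strict inequality) — a deliberate conservative behaviour.
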