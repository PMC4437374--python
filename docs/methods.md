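# Methods

## Rank scoring

Each array is normalized independently of all others. The `n` probe sets are
sorted in ascending order of signal intensity and the sorted order is
partitioned into `n_bins` contiguous blocks (default `n_bins = 100`); every
probe set in block `k` receives the integer rank score `k`. With
`n = q·n_bins + r` the first `r` blocks (the lowest signals) have size
`q + 1` and the remainder size `q`, so block sizes never differ by more than
one: a 54,675-probe array yields blocks of 546 or 547, a 45,101-probe array
yields 451 (plus one block of 452). Placing the larger blocks at the low end
is a convention — any placement satisfies the near-equality constraint — and
it is fixed so that results are bit-reproducible.

Ties are broken by a stable ascending sort with the probe set ID as the
secondary lexicographic key (input position when no IDs are given). A
deterministic tie rule is required because equal signals straddling a block
boundary would otherwise receive arbitrary scores. Two consequences worth
knowing: scores are invariant under any positive rescaling of one array's
signals, and a constant array still produces the full uniform block
structure, entirely determined by the tie order.

`n_bins` is a parameter rather than a constant so that toy problems (e.g.
10 probes in 5 bins) exercise the same code path as production-size arrays.

## RBE curves, GPL and ARS

For one probe set and one cell group of `m` samples, the rank-based
expression (RBE) curve is the empirical distribution of the probe set's `m`
rank scores: ordinate `y_s = (#samples with score s)/m`, a length-`n_bins`
dense vector that sums to 1 by construction (each ordinate times `m` is an
integer count).

Group summary statistics:

* `ARS = mean(scores)` — arithmetic mean, in `[1, n_bins]`.
* `Q1, Q3` — 25th/75th percentiles with linear interpolation between order
  statistics, the p-th quantile at position `1 + (n−1)p` in the sorted
  vector (numpy default, R type 7). The quantile convention is declared
  because the interquartile range at small group sizes depends on it.
* `GPL = Q3 − Q1` — in `[0, n_bins − 1]`, zero exactly when the central half
  of the samples share one score.

ARS is exposed both per (probe set, group) and over the whole compendium;
the compendium-wide ARS is the sample-size-weighted mean of the group ARS
values (an identity the tests check).

## Marker evaluation score

For probe set `j`, the background vector is its rank scores over **all**
samples of **all** groups; each group contributes its own score vector. The
group is deliberately included in its own background — the background is
defined over all cell groups with no exclusion — which biases MES toward 0,
increasingly so as the group's share of the compendium grows (at a 50% share
the attainable |MES| is sharply capped). Downstream comparisons should
therefore rank MES within a group, not across compendia of different
composition.

The test is the two-sided Wilcoxon rank-sum (Mann-Whitney U) test:

* For large samples: scipy's asymptotic normal approximation with tie
  correction and continuity correction. Every production-size problem
  (hundreds of background samples) takes this path.
* When the pooled sample is small enough that all
  `C(n_group + n_background, n_group)` splits can be enumerated cheaply
  (at most 50,000 combinations, which covers every pooled size ≤ 16), the
  exact permutation distribution of the statistic is used, with the
  two-sided p-value defined as the doubled smaller one-sided tail, capped
  at 1. Small toy problems therefore get exact p-values; the test suite
  checks this path against an independent enumeration oracle.

`MES = |log10 p|`, signed positive when `median(group) ≥ median(background)`
and negative otherwise. MES is NA in two cases: the p-value underflows to
floating-point zero (no clamping to the smallest representable value — the
magnitude would be fictitious), or the background scores are all identical
(the test is undefined). The constant-scores NA condition is evaluated on
the background vector, i.e. on all samples; NA is serialized as the literal
string `NA` in output tables.

One subtlety of the sign rule: when a probe set is low in *every* group but
one, each "low" group's median coincides with the background median, so the
≥ rule assigns those groups a small *positive* score rather than a negative
one. Strictly negative scores require the group median to sit below the
background median (e.g. a gene low in one group and mid-range elsewhere).

No multiple-testing correction is applied: the score is a ranking device,
not an inference.

## Electronic sorting

A sort query is (probe set, cell group, score window `[lo, hi]`). The result
is exactly the group samples whose rank score falls in the window, each with
its raw signal, score and full annotation, plus a series view that partitions
the hits by series ID and reports each series' total group sample count.
Queries operate on rank scores, never raw signals — scores are the only
cross-array-comparable currency. Multi-gene queries are out of scope.

## Detection-call calibration

Given P/M/A calls aligned with a rank matrix, the absent fraction at score
`s` is the fraction of all pooled (probe set, sample) cells with score `s`
whose call is A; scores with no cells are NA. Marginal calls count as
not-absent. The calibrated threshold is the largest `t` such that every
score below `t` has absent fraction ≥ the target (default 0.99); an NA score
breaks the qualifying run, a fully qualifying vector saturates at `n_bins`
(flagged), and `t = 1` means no undetectable zone. The per-score reading
(each score below the threshold must individually qualify) is implemented;
the full fraction vector is returned so a cumulative reading can also be
checked by the caller. Fractions are pooled over the whole compendium by
default, optionally over one group's samples.

## Marker-based sample QC

A marker panel maps each covered cell group to required markers, each marker
to one or more probe sets, with a detection threshold (panel-wide default,
per-rule override). A sample passes iff for every marker of its group at
least one probe set scores at or above the threshold; the first failing
marker (panel order) is reported. Samples of uncovered groups are neither
kept nor rejected. The admission logic (all markers required, any probe set
per marker sufficient, detectability = rank score ≥ threshold) is the
package's explicit reading of marker-based QC; alternative logics are panel
configuration, not code changes. Global array-level QC (scale factors, 3'/5'
ratios) is out of scope.

## Synthetic compendium generator

The generator emulates a curated immune-cell compendium at desk scale.
Defaults — chosen once as the package's study conditions:

* 2,000 probe sets, 5 cell groups × 60 samples, 6 series per group, 100
  bins. Small enough that the full suite runs in about a minute, large
  enough that block structure (block size 20) and group statistics are
  non-trivial.
* Background signals log-normal: per-probe location `μ_p ~ N(6, 1.5²)` in
  log-space, per-cell noise sd 0.4 — a heavy-tailed positive intensity
  distribution with stable-but-noisy per-probe percentiles, giving
  background GPL well below planted plastic levels.
* QC violation fraction 0.12 (matching the ~12% rejection rate reported for
  curated human arrays): exactly `round(0.12 · n_samples)` samples are
  forced to undetectable marker scores.
* Absent-call model: P(absent) = 0.995 at scores below 25, 0.005 otherwise;
  2% of non-absent cells are marginal. At default size each score pools
  ~6,000 cells, so the binomial error on the absent fraction (~0.001) keeps
  every sub-threshold score above the 0.99 target and calibration recovers
  the planted cutoff deterministically in practice.

Planted patterns: `marker_high` (focal group in band [90, 100], elsewhere
[4, 14]), `marker_low` (mirrored), `plastic_bimodal` (a fraction of focal
samples high [88, 98], the rest [3, 12] — a two-peaked curve with GPL ≥ 50),
`disease_shift` (high in one group, [4, 14] in its partner, [40, 60]
elsewhere).

Plants are engineered in signal space but targeted in rank space. For each
sample, each plant draws a global ascending rank position uniformly inside
its target score block; positions are made distinct; then, processing the
planted probes in position order, the `i`-th planted value is placed strictly
between the background order statistics bracketing `pos_i − i` background
values (multiple plants in one gap get distinct interior fractions). Because
the background is continuous this placement is exact: the realized rank
score equals the targeted one by construction. The generator nevertheless
ranks the finished matrix and verifies every plant against its band, raising
rather than silently degrading ground truth; an over-subscribed band
(more plants than block positions) also fails loudly.

Everything is driven by one `numpy.random.Generator` seeded from the spec,
so outputs are byte-identical for a given seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: probe-level (PM/MM) structure and true MAS5
detection p-values, cross-hybridisation, batch and lab effects correlated
with series, heterogeneous group sizes and mixed-population groups,
realistic free-text metadata, and any relationship between gene identity and
expression. Recovery results on synthetic data validate the algebra and the
pipeline's discrimination under the stated geometry, not biological
performance.

## Numerical and degenerate-input conventions

* Signals must be finite and non-negative; NaN or negative values are
  construction/validation errors naming the offending sample or coordinate.
* Fewer probes than bins is an error (the binning is undefined).
* Curve ordinates are exact ratios of integers; the 1e-12 normalization
  tolerance in tests only absorbs float summation order.
* Gene queries resolve case-insensitively on symbols and aliases, exactly on
  integer gene IDs and probe set IDs; unannotated probe sets participate in
  ranking (they occupy rank positions on the physical array) but are
  excluded from gene-level resolution.
* TSV round-trips are exact: signals are written with 17 significant digits
  and parsed with round-trip float precision.

## Known limitations

* MES attenuation from the group-in-background convention (above) is a
  property of the score's definition, kept deliberately; an
  exclude-own-group variant would change published-score semantics.
* The quantile convention for GPL at small `n` is one of several defensible
  choices; it is declared and tested rather than configurable.
* Electronic sorting returns full result objects; at compendium sizes far
  beyond the defaults a lazy/indexed backend would be preferable.
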