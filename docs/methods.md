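# Methods

## Weighted empirical ROC analysis

The evaluation unit is a table of cases `(hs_i, sp_i, w_i)` with suitability
scores `hs_i ∈ [0, 1]`, binary states `sp_i`, and strictly positive weights
`w_i` (unit by default).  The empirical ROC curve is built over the unique
score values in decreasing order: at each threshold the cumulative presence
and absence masses — counts, or weight sums in the weighted case — are
divided by the class totals to give one `(fp, tp)` vertex per unique score,
preceded by the origin `(0, 0)` (sentinel threshold `+inf`).  Cases tied on
a score collapse into one vertex, so mixed-class ties appear as diagonal
segments.  The AUC is the trapezoidal sum over consecutive vertices; with
unit weights it coincides with the Mann–Whitney form (concordant
presence–absence pairs, ties counting one half) to machine precision, with
or without ties, and the weighted AUC coincides with the weighted
pair-enumeration form.  Because the cumulative masses are normalised by the
class totals, only relative within-class weights matter: per-class constant
weights reproduce the unweighted statistics and global rescaling is a
no-op.

Se\* scans the curve vertices for the minimal `|Se − Sp|` and returns
`(Se + Sp)/2` there.  Three deliberate choices where the convention is
genuinely open:

* **Candidate set.**  Only vertices compete (the origin included, with
  Se = 0, Sp = 1); no interpolation into the interior of diagonal
  segments.
* **Tie-break.**  Among vertices with equal `|Se − Sp|`, the highest
  `(Se + Sp)/2` wins; among remaining ties, the highest threshold.  This is
  deterministic and favours the better-discriminating cut.
* **Score equality** is exact float comparison: scores are data, not
  computed quantities, so no tolerance is applied.

Degenerate inputs (a single class, non-positive weights, scores outside
`[0, 1]`) are hard errors rather than NaN returns, because silent NaNs
would propagate into simulation summaries.

## Uniform statistics

uAUC and uSe\* weight each case by the inverse occupancy of its suitability
bin.  Bins are equal-width over the fixed support `[0, 1]` (10 by default)
— not the data range — because fixed edges are what makes weights, and
hence scores, comparable across datasets.  Bins are half-open `[lo, hi)`
with the last bin closed so `hs = 1` belongs to the top bin; edges are
computed as `k / n_bins`, which keeps an edge like 0.3 on the same binary
double as the literal, so two-decimal scores land in the intended bin.
Empty bins are skipped; occupancy counts both classes.

The **direct route** evaluates the weighted statistics with these weights —
a pure function of the data and the bin count.  The **legacy bootstrap
route** draws cases with replacement with probability proportional to the
weights and averages the unweighted statistic over replicates (1,000 by
default; the same default as the CI resampling, configurable).  The two
routes agree to well under 0.01 at n = 1,000 with 2,000 replicates, but the
direct route is deterministic and less biased at small n.

Resampling is implemented without materialising replicates: a bootstrap
replicate is a multinomial multiplicity vector over the cases, and the
unweighted statistic of the resampled multiset equals the
multiplicity-weighted statistic of the base data (duplicate copies collapse
into the same ROC vertex).  The base data is sorted and tie-grouped once
and all replicates are evaluated as rows of a weight matrix; this is
distributionally identical to naive resampling (verified in the tests
against a materialised-resample oracle) and makes the simulation study
feasible on a single CPU.  Replicates in which a class vanishes are
redrawn, with a cap of 100 rounds before erroring; discarding them silently
would bias small-n results.

**Percentile CIs** (direct route only) resample cases with *equal*
probability, recompute the inverse-occupancy weights on every replicate —
the weights are part of the estimator, so their sampling variability
belongs in the interval; a regression test guards the recomputation — and
take the empirical `α/2` and `1 − α/2` quantiles (numpy's default linear
interpolation) of the replicate distribution.

## Simulation study

Four scenario distributions for `hs` on `[0, 1]` span qualitatively
different representativeness situations:

| scenario | mixture |
|---|---|
| A | ½ truncnorm(μ=0, σ=0.25) + ½ truncnorm(μ=1, σ=0.25) |
| B | truncnorm(μ=0, σ=0.6) |
| C | truncnorm(μ=0.5, σ=0.3) |
| D | ½ truncnorm(μ=0, σ=0.05) + ½ uniform |

Truncated normals are sampled exactly on `[0, 1]` (scipy's `truncnorm`,
not clipping); mixture component sizes follow the stated fractions with
cumulative rounding.  Labels are generated by `sp_i = 1` iff an independent
uniform draw falls below `hs_i`, i.e., a perfectly calibrated model, which
fixes the population values of the uniform statistics at 0.83 (uAUC) and
0.75 (uSe\*) for every scenario: with uniform suitability, presences have
density `2x` and absences `2(1 − x)`, giving `P(hs_pres > hs_abs) = 5/6`
and `Se = Sp = 3/4` at threshold ½.  The constants are stored at the
two-decimal precision conventional in this literature and are not
recomputed.  Scenario D's uniform component is the standard uniform on
`[0, 1]`.

The bias experiment simulates datasets, discarding and redrawing any
single-class draw (the redraw count is reported), and summarises each
statistic by its median, bias (median minus reference, uniform statistics
only), IQR and mean.  The coverage experiment records the fraction of
simulated datasets whose percentile CI contains the reference value; both
statistics share the same resampling draws.  Randomness uses one seed per
experiment with per-iteration child streams (`SeedSequence.spawn`), so
reports are bit-reproducible and independent of loop chunking.

## Problem sizes and what the tests show

The test suite and the acceptance script run the study at reduced scale,
chosen as the package's own default verification budget: reference
recovery over 1,000 iterations at n = 1,000 per scenario (tolerance 0.015
on means); the bias bound over 2,000 iterations per (scenario, n ∈ {30,
150}) cell with both routes; coverage over 100 datasets × 1,000 resamples
at n = 30.  The full grid (10 sample sizes up to 10,000, 10,000 iterations
per cell) is reachable through the same drivers via the CLI flags.

Coverage checks compare one finite Monte-Carlo estimate against another:
a 100-dataset coverage proportion has a binomial standard deviation of
roughly 0.02–0.03, and published reference coverages carry the same noise,
so individual comparisons can sit 1–2 SD apart without indicating an
implementation difference.  The direct uAUC interval at n = 30 under
skewed score distributions under-covers somewhat (misses are mostly
intervals lying entirely above the reference, reflecting the method's
small positive small-n bias); this is a property of the estimator, not of
the implementation, and was confirmed by an independent re-implementation
of the full pipeline.

The generator emulates a perfectly calibrated model with independent
cases.  Real evaluations violate both: spatial autocorrelation makes cases
dependent, and real models are miscalibrated, so passing these tests shows
the estimators and intervals behave as designed under the stated sampling
model — not that nominal coverage holds on real SDM evaluations.  The
package also does not address presence-only data, partial AUC,
cost-sensitive ROC weighting of false positives against false negatives,
or data-quality-derived weights; weights are accepted as given.
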