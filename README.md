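# uniroc

Case-weighted and uniform ROC statistics for evaluating presence–absence
species distribution models (SDMs).

## The problem

An SDM produces a continuous habitat-suitability score `hs ∈ [0, 1]` per
site, evaluated against observed presence/absence `sp ∈ {0, 1}`.
Discrimination is usually summarised by the area under the empirical ROC
curve (AUC) or by sensitivity-star (Se\*), the mean of sensitivity and
specificity at the threshold where they are closest.  Both depend strongly
on the *distribution* of suitability values in the evaluation dataset — the
representativeness effect — so scores from different datasets or regions are
not comparable even when the species responds to the environment
identically.

`uniroc` addresses this with **case weighting** along the ROC curve.  For a
weight `w_i > 0` per case, the weighted true/false positive rates accumulate
weights instead of counts over the unique thresholds, and

```
wAUC = Σ_k (fp.w_{k+1} − fp.w_k) · (tp.w_k + tp.w_{k+1}) / 2
```

(the trapezoidal rule, which also handles tied scores as diagonal
segments).  Only *within-class relative* weights matter.  The **uniform
statistics** uAUC and uSe\* are the special case where `[0, 1]` is cut into
10 equal-width bins and `w_i = 1 / n(bin(i))`, which reweights the score
distribution to uniform and harmonises scores across datasets: under a
perfectly calibrated model their population values are 0.83 and 0.75
regardless of the suitability distribution.

Two routes are provided for the uniform statistics: the **direct weighted
trapezoidal estimator** (deterministic, no resampling) and the **legacy
stratified bootstrap** (resample cases with probability proportional to
weight, average the unweighted statistic).  Percentile bootstrap confidence
intervals for the direct statistics recompute the bin weights on every
replicate.  A simulation module generates calibrated datasets under four
suitability-distribution scenarios (A–D) and measures bias, IQR, and CI
coverage.

## Worked example

The bundled 20-case table (11 presences, 9 absences, scores 1.00…0.05):

```python
>>> import uniroc as u
>>> data = u.table1()
>>> round(u.trapezoidal_auc(u.build_roc(data)).estimate, 3)
0.667
>>> round(u.mann_whitney_auc(data).estimate, 3)   # identical by construction
0.667
>>> w = u.table1_weights()
>>> round(u.weighted_auc(data.with_weights(w["w.b"])).estimate, 3)
0.634
>>> round(u.weighted_auc(data.with_weights(w["w.c"])).estimate, 3)
0.732
>>> u.uauc_direct(data).estimate
0.710789766407119
```

`w.b` down-weights the lowest-scored absence (an "easy" case), so the wAUC
drops below the AUC; `w.c` down-weights the highest-scored absence (a
"hard" case), raising it.  The uniform AUC (0.711) is the weighted AUC
under inverse-bin-occupancy weights — here bin occupancies are
`[1,2,2,2,2,2,2,2,2,3]`, so e.g. the single case in the lowest bin gets
weight 1 and the three top-bin cases get 1/3 each.

From the shell:

```sh
uniroc fixtures --out-dir data/
uniroc evaluate data/table1.csv
uniroc uniform data/table1.csv --ci --reps 1000 --seed 1
uniroc simulate bias --scenario C --n 150 --iters 2000 --seed 42 --out bias.json
uniroc simulate coverage --scenario B --n 30 --outer 100 --reps 1000 --seed 42
```

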