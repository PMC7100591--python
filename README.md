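# morphosig

Assessment of discrete morphological character partitions over
molecularly derived, time-calibrated phylogenies.

Morphological characters are the only phylogenetic evidence for fossil
taxa, but they violate the assumptions equal-weights analyses rest on:
rates vary between characters, rates vary within characters, and
characters do not evolve independently.  `morphosig` quantifies all three
for characters grouped by skeletal region (teeth, skull, vertebrae,
forelimb, hindlimb, soft tissue), using a time tree built from molecular
data as an independent benchmark, and asks which partitions differ — the
framework behind the finding that mammalian dental characters evolve
faster (hence more homoplastically) than other partitions without being
less independent.

Per character (k observed states, tree branch lengths in Myr):

* **Phylogenetic signal** — Pagel's λ ∈ [0, 1], fitted jointly with a
  single Mk rate by profile likelihood on the λ-transformed tree
  (internal branches × λ, pendant branches stretched to preserve tip
  depths).  λ = 1: state distribution tracks the tree; λ = 0: independent
  of it.
* **Within-character rate homogeneity** — equal-rates (ER, 1 parameter)
  vs all-rates-different (ARD, k(k−1) parameters) Mk models compared by
  Akaike weights, `w_i ∝ exp(−Δᵢ/2)`, AIC = 2·n_free − 2·lnL.
* **Evolutionary rate** — the ER rate if ER wins; otherwise the mean of
  the ARD rates weighted by realised transition counts from 1000
  stochastic maps.
* **Independence** (binary pairs, within partition) — Pagel's
  correlated-evolution test: independent (4-rate) vs dependent (8-rate)
  four-state models, double transitions disallowed, scored by the
  independent model's Akaike weight.

Partition-level comparison uses a maximum-likelihood Gaussian model pair
(null: one mean; H1: separate mean for the focal partition) scored by
Akaike weights with the indicator coefficient giving the direction, plus
Kendall's tau-b rank correlations between metrics.

Likelihoods use Felsenstein pruning with per-node rescaling; trees may
contain polytomies; missing scores (`?`, `-`, polymorphic) are handled
throughout, including the rule that excludes characters with more than
25% unknown taxa.  See `docs/methods.md` for the full model description
and numerical choices.

## Worked example

Generate a synthetic dataset with known truth (32 taxa, six partitions of
five binary characters; teeth evolve at 0.02/Myr with λ = 0.3, the rest
at 0.002/Myr with λ = 1; 10% missing scores), then run the pipeline:

```sh
morphosig simulate --n-taxa 32 --seed 1 --out data/
morphosig all --tree data/tree.nwk --matrix data/matrix.nex \
    --partitions data/partitions.csv --seed 1 --out results/
```

or in Python:

```python
import morphosig as ms

ds = ms.make_fixture(seed=1)
tree, matrix, _ = ms.reconcile(ds.tree, ds.matrix)
cfg = ms.RunConfig(seed=1)
assessments, excluded = ms.run_assess(tree, matrix, ds.partitions, cfg)
reports, summary = ms.run_compare(assessments, [], ds.partitions)
print(summary.table[["partition", "median_lambda", "median_rate"]])
print(reports["rate"][["focal", "beta", "w_h1", "direction"]])
```

which prints (seed 1):

```
     partition  median_lambda  median_rate
0     forelimb       1.000000     0.016215
1     hindlimb       1.000000     0.009510
2        skull       0.999653     0.020903
3  soft_tissue       1.000000     0.003825
4        teeth       0.099960     2.808469
5    vertebrae       1.000000     0.002638
```

```
         focal      beta      w_h1 direction
0     forelimb -1.284037  0.303389      none
1     hindlimb -1.278355  0.303073      none
2        skull -1.286480  0.303526      none
3  soft_tissue -1.300860  0.304336      none
4        teeth  6.455774  0.981784    higher
5    vertebrae -1.306042  0.304631      none
```

The fast, signal-degraded teeth partition shows the lowest median λ̂ and
a median assigned rate far above every other partition; the GLS
comparison puts nearly all Akaike weight on the H1 model for teeth with a
positive coefficient (`direction=higher`).  Note the apparent teeth rate
exceeds the generating 0.02/Myr by orders of magnitude: a rate-only Mk
fit absorbs the λ = 0.3 signal degradation as extra rate — the λ–rate
confound this style of analysis reports as a strong negative λ–rate
correlation (here Kendall's τ ≈ −0.59, p ≈ 5 × 10⁻⁵).

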