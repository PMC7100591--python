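# Methods

`morphosig` assesses how well discrete morphological characters behave as
phylogenetic evidence, using an independently derived, time-calibrated
(molecular) phylogeny as the benchmark.  Characters are grouped into six
skeletal-region partitions (teeth, skull, vertebrae, forelimb, hindlimb,
soft tissue) and each partition is scored on four axes: phylogenetic
signal, within-character rate homogeneity, evolutionary rate, and pairwise
independence.

## Data preparation

Trees (Newick / NEXUS) and character matrices (NEXUS STANDARD data) are
reconciled before analysis:

* taxa absent from either source are dropped; the tree is pruned with
  degree-2 nodes suppressed and their branch lengths summed, so surviving
  root-to-tip distances are unchanged;
* characters invariant over the surviving taxa are dropped;
* per character, taxa with unknown scores are dropped from the tree, and a
  character is excluded outright when *more than* 25% of the reconciled
  taxa are unknown (exactly 25% is kept) or fewer than 3 known scores
  remain.

Unknown (`?`), gap (`-`) and polymorphic/ambiguous scores (`{01}`) are all
treated as missing.  The analyses below only distinguish known from
unknown, and matrices of this kind rarely give the gap a separate meaning;
the choice is recorded in every output file's metadata header.  Observed
states are recoded to dense integers `0..k-1` per character.  Polytomies
are accepted everywhere; no likelihood code assumes bifurcation.

## Mk likelihoods

A character with k states evolves by a continuous-time Markov chain with
rate matrix Q (units: expected transitions per Myr).  Two
parameterisations are fitted per character:

* **ER** — one shared rate for every ordered state pair (1 free
  parameter);
* **ARD** — an independent rate for every ordered pair (k(k−1) free
  parameters).

Log-likelihoods come from Felsenstein pruning with per-node rescaling of
partial likelihoods (scale factors accumulated in log space), so slow
rates on deep trees do not underflow.  Missing tips contribute all-ones
partials.  ER transition probabilities use the closed form
`p_ii(t) = 1/k + (1−1/k)e^{−kqt}`; general Q uses the matrix exponential
(batched eigendecomposition with an `expm` fallback for ill-conditioned
cases).

The root prior is uniform over the k states (configurable to the
stationary distribution of Q); the choice is written into output
metadata.  Model support uses AIC = 2·n_free − 2·lnL (not AICc) and
Akaike weights `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`.  The ER Akaike weight
is the per-character measure of within-character rate homogeneity.  Exact
AIC ties resolve to the simpler (ER) model.

### Optimisation

Rates are optimised in log space with L-BFGS-B, bounds
[1e−8, 1e3] transitions/Myr, from a parsimony-based start (Fitch change
count divided by total tree length) plus seeded random restarts (5 by
default; the large simulation studies in the test-suite and acceptance
script use 1–2 restarts, which the wide likelihood basins of these
one-to-eight-parameter problems make sufficient).  Above the saturation
rate the likelihood is flat in any rate, so after optimisation each rate
is bisected down to the smallest value whose log-likelihood stays within
1e−6 of the optimum.  This tie-break makes saturated fits deterministic
(otherwise the reported rate would be an arbitrary point on the plateau)
and leaves identified optima untouched.

## Phylogenetic signal (Pagel's lambda)

Lambda rescales internal branches by λ ∈ [0, 1] while stretching pendant
branches to preserve each tip's depth exactly; λ = 1 leaves the tree
unchanged, λ = 0 yields a star.  Signal is estimated by jointly fitting
(λ, q) with a single ER rate — the minimal lambda model for discrete
characters: a profile over an 11-point λ grid on [0, 1], re-optimising q
at each point, refined by a bounded scalar search between the
neighbouring grid points.  The transform requires an ultrametric tree
(tip depths equal within 1e−6 relative).

**Identifiability caveat.** For binary characters whose states are near
stationary frequencies and saturated (e.g. states assigned by fair coin),
the profile in λ is almost flat and chance concordance of cherries can
pull the ML estimate to λ = 1 with a large rate.  Characters generated by
a genuinely signal-free process at realistic rates (the generator's λ = 0
setting) are estimated near 0; fully saturated balanced characters are
not a regime in which λ̂ is informative.

## Rate assignment

If ER carries at least as much Akaike weight as ARD, the character's rate
is the fitted ER rate.  If ARD wins, the character is stochastically
mapped under the ARD MLE Q (1000 maps by default): node states are drawn
from their joint conditional distribution given the tips, and each
branch's path is simulated conditional on its endpoints — rejection
sampling with a 1000-attempt cap per edge, falling back to exact
uniformization sampling (jump count drawn from
P(N=n|a,b) ∝ Pois(n; Λt)(R^n)_ab with R = I + Q/Λ, intermediate states
from the conditioned uniformized chain, virtual jumps discarded).  The
assigned rate is then the mean of the fitted pairwise rates weighted by
the mean realised count of each ordered transition; pairs never realised
contribute nothing, and if no transitions are realised at all the
unweighted mean is used and flagged.  Mapping uses the AIC-winning model's
Q; the per-character map seeds fan out deterministically from the run's
master seed, so subset runs reproduce full-run rows.

## Pairwise independence

For every unordered pair of binary characters within a partition, the two
characters are recoded as one four-state joint character
(00→0, 01→1, 10→2, 11→3) and two models are compared on the taxa known in
both members (the 25% exclusion rule applies to the pair's joint unknown
fraction):

* independent — 4 rates (each trait's gain/loss unaffected by the other);
* dependent — 8 rates (each trait's gain/loss may differ with the other's
  state).

Double transitions are impossible in both models.  Comparison is by AIC
(n_free 4 vs 8); the independent model's Akaike weight is the pair's
independence score.  Because the models are nested, the dependent fit is
restarted from the independent optimum whenever multi-start optimisation
leaves it below the independent log-likelihood.  Pairs are formed within
partitions (a cross-partition flag exists); a seeded `max_pairs`
subsample supports desk-scale runs.

## Partition-level statistics

Per-character metrics (λ̂, ER weight, assigned rate) and per-pair
independence weights are compared across partitions with a two-model
Gaussian comparison fit by maximum likelihood: null = one mean for all
partitions; H1 = a separate mean for the focal partition (indicator
regression).  With no correlation structure this "GLS" is ML-OLS with
closed-form log-likelihoods (−n/2·(log 2πσ̂² + 1), σ̂² the ML variance);
AIC uses 2 free parameters for the null and 3 for H1 (means + variance) —
the counts that reproduce the published tables' arithmetic.  ML rather
than REML is used because REML likelihoods are not AIC-comparable across
mean structures.  The focal partition is called `higher`/`lower` only
when H1 out-weighs the null, with the sign of the indicator coefficient
(= mean(focal) − mean(rest)) giving the direction.

Rank correlations (λ̂ vs rate, λ̂ vs ER weight across characters;
character count vs each per-partition median across partitions) use
Kendall's tau-b, the tie-corrected variant that both common statistical
environments default to, with a two-sided p-value.  Medians use the
midpoint convention.  No multiple-testing correction is applied across
the per-partition tests (a Holm flag is available to users).

## Synthetic data

The generator provides every input the pipeline needs, with known truth:

* **Trees** — pure-birth (Yule) trees rescaled to depth 100 Myr, the
  timescale of the mammalian benchmark trees.  Tree shape is not a
  quantity under test, so birth-death extinction is not modelled.
* **Characters** — evolved edge-by-edge with exp(Q·t) from a uniform root
  state, on the λ-transformed tree when signal degradation is wanted.
* **Pairs** — evolved jointly under the dependent four-state chain.
* **Missingness** — applied uniformly at random per character (the
  analysis treats missingness only through the 25% rule, so structured
  missingness is not emulated).

The default fixture has 32 taxa and six partitions of five binary
characters: teeth evolve at 0.02/Myr with λ = 0.3, all other partitions
at 0.002/Myr with λ = 1 — the fast partition is also the signal-degraded
one, mirroring the empirical association between elevated rates and
eroded signal that the analysis is designed to detect (a rate-only Mk fit
absorbs degraded signal as extra apparent rate, so the two settings
reinforce rather than cancel).  10% of scores are missing; two strongly
dependent pairs (the second trait's switch rate 50× higher in one context
of the first) are planted in the forelimb partition.  Characters are
redrawn until variable among known scores, as real matrices contain no
invariant columns.

What passing recovery tests show — and what they do not: the generator
matches the analysis models exactly (no ascertainment beyond variability,
no correlated missingness, no among-character rate autocorrelation, no
model misspecification), so recovery results certify the estimation
machinery, not robustness of the method on real matrices.

## Problem sizes used in the automated checks

Exactness properties run on 1000 random trees of 3–6 tips against a
brute-force enumeration oracle.  Recovery studies use: 500 (tests) / 300
(acceptance script) binary ER characters on a 128-tip tree (true rate
0.005/Myr, median recovered within 20%); 100/50 signal-free characters on
64 tips (median λ̂ ≤ 0.2); 100/60 independent and strongly dependent
pairs on 64 tips (median independent-model weight above 0.5 and below
0.2 respectively); and the default fixture over 5 seeds for the
partition-level GLS direction check.  Stochastic maps use M = 250 in
these studies (M = 1000 is the pipeline default).

## Known limitations

* λ is weakly identified for saturated, frequency-balanced binary
  characters (see above).
* Assigned rates for characters whose best model is saturated sit at the
  plateau edge; they are deterministic but should be read as "at least
  this fast".
* The GLS comparison treats characters as exchangeable observations;
  it inherits no phylogenetic covariance (characters, not taxa, are the
  rows).
* The pairwise test is restricted to binary characters by construction.
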