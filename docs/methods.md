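# Methods

This note documents the model, the numerical choices and the known
limitations of `coevonet`, in the spirit of a statistical software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The gain/loss model

Presence (1) / absence (0) of a gene family evolves along a rooted
bifurcating species tree as a stationary continuous-time Markov chain with
generator

```
Q = [[-g, g], [l, -l]]
```

gain rate `g` and loss rate `l` in events per unit of *rescaled* branch
length. The chain has stationary frequencies `pi1 = g/(g+l)`,
`pi0 = l/(g+l)` and the closed-form transition probabilities
`P01(t) = pi1 (1 - e^{-(g+l)t})`, `P11(t) = pi1 + pi0 e^{-(g+l)t}` (and
symmetrically). The root prior is the stationary distribution — the process
is stationary, so no extra root parameters exist.

**Rate variability.** Families differ in how labile their gene content is.
We use K equiprobable rate categories (default K = 4); category k multiplies
`g` and `l` by the k-th quantile medians (quantiles `(k+0.5)/K`) of mean-1
gamma distributions with shapes `alpha_gain` and `alpha_loss`. The gain and
loss multipliers are *paired* (same quantile on both axes), which captures
"fast vs slow families" with two shape parameters; a factorial combination
would square the category count for little extra realism at this data size.
The per-gene likelihood is the uniform mixture `(1/K) sum_k L_k`, each `L_k`
computed by Felsenstein pruning with per-node rescaling against underflow.

**Identifiability.** Only the products `rate * rho * t` enter the
likelihood, so the overall rate scale is not identifiable separately from
the branch-scale factor `rho`. We fix `g + l = 2` during optimization and
let `rho` (bounds 1e-3..1e3) absorb the conversion from
substitutions-per-site branch lengths to gain/loss time; the free shape of
the process is the gain fraction `p = g/(g+l)` (bounds 0.01..0.99).

**Fitting.** Coordinate-wise bounded Brent search over `p`, `rho` (log
scale) and, for K > 1, `alpha_gain` and `alpha_loss` (log scale, bounds
0.05..100), cycled until the total log-likelihood improves by less than
1e-4 (default; 50-cycle cap, non-convergence warns and returns the best
point). The procedure is deterministic given its configuration. No
ascertainment-bias correction is applied for families absent from every
genome (which are unobservable in real data); this is a recorded limitation
— with realistic rates the correction is small, and the exchangeability
filter removes the low-signal regime where it matters most.

## Stochastic mapping

For each family and branch we want `E[#gains | leaves]` and
`E[#losses | leaves]`. With two states these are exact integrals: writing
`r = g + l` and `P_ij(s) = pi_j + e^{-rs}(delta_ij - pi_j)`, the joint
expectation of a gain with endpoint pair (a, c) on a branch of length t is

```
J01[a,c] = g * Int_0^t P_a0(s) P_1c(t-s) ds
```

which reduces to elementary terms in `t`, `e^{-rt}` and `(1-e^{-rt})/r`
(computed with `expm1` for small `rt`). Conditional on the endpoints the
expected count is `J/P_ac(t)`; endpoint posteriors come from inside/outside
pruning passes. These formulas are numerically stable over the whole float64
range, so no uniformization fallback is needed. Expectations — not sampled
realizations — populate the event vectors, matching the use of the vectors
in a correlation statistic. Rate categories are averaged with each gene's
*posterior* category weights rather than the uniform prior: the mapping
should condition on everything observed about the gene.

Families absent from every leaf get an all-zero vector and a degenerate
flag: no events are inferable for them. Zero-length branches (including
those inserted to resolve polytomies) receive exactly zero expected events,
which is why the arbitrary polytomy resolution cannot affect inference.

The per-gene **exchangeability** is `(total gains + total losses)/2`.

## The pair test

The statistic is the Pearson correlation between two `4n-4` event vectors.
Its null distribution depends strongly on how many events the genes
experienced — low-signal pairs reach extreme correlations by chance — so:

* Only genes with exchangeability strictly above 5 events are tested
  (strictly: a tie at the threshold is excluded).
* The bootstrap null is *binned by the pair's minimal exchangeability*.
  Default bin edges: 5, 7.5, 10, 15, 20, 30, 50, inf — roughly geometric,
  configurable. Ties at a bin edge go to the lower bin. Each bin should
  hold at least 10,000 simulated independent pairs by default; bins
  unreachable under the model within the simulation budget are flagged
  with their shortfall rather than silently extrapolated.
* P-values are one-sided for positive correlation with the add-one rule
  `P = (#{null >= r} + 1)/(N + 1)`, so P is never zero — a requirement for
  meaningful BH with finite null samples. Positive correlation is the
  co-evolution signal (co-gain and co-loss); anti-correlated avoidance is a
  different phenomenon and is excluded by default (`two_sided=True` tests
  |r| for exploration).
* Benjamini–Hochberg step-up at FDR 0.01 (default) decides significance;
  q-values are the usual monotone adjusted P-values.

A practical sizing constraint follows from the add-one floor `1/(N+1)`:
BH at level q with m tests can only reject if P-values near `q/m` are
representable, so the per-bin null size N must be at least of order
`m/(k q)` for k expected discoveries. The acceptance script sizes its
small study accordingly (about 1,000 tests against a 100,000-sample null).

## The simulator

`simulate_genes` draws the root state from the stationary distribution of a
uniformly chosen rate category and evolves each branch by exact Gillespie
simulation (exponential waiting times), so the *true* latent event counts
per branch are available for validation. The same engine drives the
parametric-bootstrap null, which therefore sees data generated by exactly
the process the mapping assumes.

`simulate_coupled_pair` is a validation device (no counterpart in the
inference): gene B shares gene A's rate category, copies A's root state
with probability `coupling`, and on each branch copies A's event
realization with probability `coupling` provided B enters the branch in
A's entry state (otherwise A's realization is not a valid trajectory for B
and the branch is simulated independently). `coupling = 0` reduces by
construction to two independent genes; `coupling = 1` duplicates the
history. It is used for power and ranking checks only, never for the null.

**What the simulator does and does not emulate.** It generates exactly the
model's world: binary presence/absence, independent families (or pairwise
branch-coupled ones), homogeneous rates along the tree, a correct tree.
Real data add gene-family copy-number dynamics, annotation error,
correlated transfer of whole operons among many families at once, tree
uncertainty and lineage-specific rate shifts. Passing tests therefore
demonstrate internal correctness and calibration under the model, not
robustness to model violation. Default simulated study conditions are a
32-leaf random-join tree with exponential branch lengths of mean 0.3–0.35
substitutions/site and `g = l` or `g:l = 1:2` — sizes at which typical
family exchangeability sits near 10 events, comfortably above the
threshold of 5, as in a well-powered slice of real gene-content data.

## Network statistics and clustering

* Average degree is `2E/N` over **all** nodes, isolates included; the
  fraction of connected genes uses the same denominator.
* The Watts–Strogatz clustering coefficient averages local transitivity
  over non-isolated nodes, with degree-1 nodes contributing 0. Whether
  isolates enter the average changes the statistic; it is an explicit flag
  (`include_isolates`, default False).
* The power-law diagnostic is OLS of `log10(count)` on `log10(degree)`
  over degrees >= 1; fewer than three distinct degrees is flagged
  unreliable.
* The Poisson goodness-of-fit is a chi-square test against
  Poisson(mean = average degree), adjacent cells pooled until every
  expected count is >= 5, one degree of freedom spent on the estimated
  mean.
* Clustering is cluster editing: minimize edge insertions plus deletions
  to disjoint cliques. The heuristic is deterministic: connected components
  first (edits never pay across components), then within each component
  greedy agglomeration seeded in decreasing-degree order (a node joins the
  cluster minimizing `|C| - 2k`, ties broken toward merging) followed by
  node-move refinement passes in canonical node order repeated to a fixed
  point (each pass strictly lowers the cost, so this terminates). On small
  graphs the heuristic is within one edit of the exhaustive optimum (tested
  property); a single refinement pass was not sufficient for that bound,
  which is why refinement iterates. No attempt is made to reproduce any
  particular published heuristic's exact output — what is fixed is the
  editing objective, not the search strategy.

## Network comparison

Overlap of the co-evolution network C with an external network X over the
same m genes: frequency `|X|/U` with `U = C(m,2)`, conditional frequency
`|X∩C|/|C|`, enrichment ratio = conditional frequency / frequency
(estimating `Pr(edge in X | edge in C)/Pr(edge in X)`), and a two-sided
Fisher exact P-value (probability-mass rule — the standard two-sided
convention) on the 2×2 pair classification. The universe is all `C(m,2)`
pairs over the full gene set, not only tested pairs, so frequencies match
the natural baseline. With an annotation map, the analysis can be repeated
on functionally informative co-evolution edges (both endpoints sharing a
category); edges with unlabeled endpoints are excluded and tallied.

## Numerical and degenerate-input conventions

* Pearson correlation of a constant vector is undefined and returned as
  NaN (never silently 0); such pairs are dropped from results with a
  warning.
* Matrix cells must be literally `0` or `1`; anything else is a format
  error with its row and column — no imputation.
* Branch lengths are required on all non-root edges; internal labels and
  support values are ignored. Polytomies (including a trifurcating root)
  are resolved deterministically with zero-length branches.
* Branch indexing is preorder from the root with children in Newick file
  order, so a given Newick string always produces the same 4n-4 vector
  layout.
* All stochastic procedures take explicit seeds; identical seed and
  configuration give bit-identical output (the Gillespie engine draws for
  every gene each iteration regardless of which genes remain active,
  keeping the random stream alignment independent of the data).

## Known limitations

* Presence/absence only: co-evolution expressed through correlated family
  *size* changes (expansions/contractions) is invisible to the model.
* No explicit pairwise co-evolution model: dependence is detected as
  deviation from independence, not estimated as an interaction parameter.
* The bootstrap null conditions on the fitted model; model misfit (e.g.
  unmodeled branch-heterogeneous rates) propagates into the null.
* No ascertainment correction for all-absent families (see above).
* Enrichment comparisons treat external networks as given edge lists;
  their own error rates are not modeled.
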