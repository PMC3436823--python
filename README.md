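# coevonet

Detection of co-evolving gene families from phyletic patterns.

Prokaryotic genomes gain genes (mostly by horizontal transfer) and lose them
(e.g. through reductive evolution) throughout their history. Gene families
that function together — subunits of a flagellum, a secretion system, an
ATP synthase — tend to be gained and lost *together*, so correlated gain/loss
histories are a strong signal of functional association. `coevonet` infers
those histories from a phyletic pattern (a genes × genomes 0/1
presence/absence matrix) and a rooted species tree, tests every pair of gene
families for significantly correlated histories, and builds and analyzes the
resulting co-evolutionary network. It is aimed at comparative genomicists
and systems biologists who want phylogeny-aware functional-association
predictions from gene-content data alone.

## Method

1. **Gain/loss model.** Presence/absence of each family evolves along the
   tree as a stationary two-state continuous-time Markov chain with gain
   rate *g* (0→1) and loss rate *l* (1→0), stationary frequencies
   π₁ = g/(g+l), π₀ = l/(g+l). Rate variability across families is modeled
   by K equiprobable categories of paired mean-1 gamma multipliers (shapes
   α_g, α_l), and a branch-scale factor ρ converts the input branch lengths
   (substitutions/site) into gain/loss time units. All free parameters
   (g : l ratio, α_g, α_l, ρ) are estimated by maximum likelihood with
   Felsenstein's pruning algorithm.

2. **Stochastic mapping.** For every family and branch, the posterior
   expected numbers of gain and loss events are computed exactly (two
   states admit closed-form conditional expectations — no sampling). A tree
   with *n* leaves has 2*n*−2 branches, so each family becomes a vector of
   length 4*n*−4: expected gains per branch, then expected losses. The
   family's **exchangeability** is the average of its total expected gains
   and total expected losses — how much gain/loss signal it carries.

3. **Pair test.** The statistic for a pair is the Pearson correlation of
   the two 4*n*−4 event vectors. Only families with exchangeability > 5
   events are tested (low-signal families reach extreme correlations by
   chance). The null distribution is built by parametric bootstrap —
   independent pairs simulated under the fitted model, mapped identically,
   binned by their minimal exchangeability — and each observed pair gets a
   one-sided empirical P-value from its own bin. Significance is decided by
   Benjamini–Hochberg FDR (default 0.01).

4. **Network analysis.** Significant pairs form an undirected network over
   all families. The package reports degree statistics, the Watts–Strogatz
   clustering coefficient, a log–log power-law regression and a Poisson
   goodness-of-fit test of the degree distribution, partitions the network
   by greedy cluster editing (transitivity clustering), and quantifies
   overlap with external networks (frequency, conditional frequency,
   enrichment ratio, Fisher's exact test), optionally restricted to
   functionally informative edges.

## Worked example

```python
import numpy as np
import coevonet as cn
from coevonet.simulate import random_tree, SimConfig, simulate_dataset

tree = random_tree(32, np.random.default_rng(0), mean_length=0.35)
model = cn.GainLossModel(gain=1.0, loss=1.0, rho=1.0, n_categories=1)
pattern, _, truth = simulate_dataset(
    tree, model, SimConfig(seed=42, n_genes=30, n_coupled_pairs=3, coupling=0.9)
)
det = cn.CoevolutionDetector(
    tree, model=model, fdr=0.01, null_per_bin=100_000, max_null_pairs=400_000, seed=1
).fit(pattern)
res = det.results_
print(f"tested pairs:      {len(res)}")
print(f"significant pairs: {res['significant'].sum()}")
print(res.nsmallest(4, 'pvalue')[['gene_a','gene_b','r','min_exch','pvalue','significant']]
      .to_string(index=False, float_format=lambda x: f"{x:.4g}"))
```

Output:

```
tested pairs:      630
significant pairs: 3
gene_a gene_b      r  min_exch  pvalue  significant
P0001a P0001b 0.9697     12.82   1e-05         True
P0002a P0002b      1     14.45   1e-05         True
P0003a P0003b 0.9679     13.66   1e-05         True
 G0002 P0001a 0.8519     12.85 0.00034        False
```

Thirty independent background families plus three pairs simulated with 90%
branchwise-shared histories (`P000*a`/`P000*b`): all 630 candidate pairs are
tested, and exactly the three planted pairs are significant at FDR 0.01.
Each planted pair's event-vector correlation (0.97–1.0) exceeds everything
in its null bin (P = 1/100001); the strongest background pair (r = 0.85)
is comfortably non-significant.

The same pipeline is available from the shell:

```sh
coevonet run --tree tree.nwk --pattern pattern.tsv --out rundir --seed 1
```

which writes the fitted model, event and exchangeability tables, null
table, per-pair results, significant edges, cluster memberships and a
summary JSON into a self-describing run directory (subcommands `fit`,
`map`, `simulate`, `test`, `network`, `compare` expose the stages
individually).

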