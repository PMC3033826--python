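# odnet

Structural analysis of how metabolic reaction networks overlap across many
organisms, together with a neutral model of metabolic network growth.

## The problem

Bacterial metabolisms evolve by gaining and losing enzyme-coding genes, and
different species therefore share different parts of their reaction
repertoires.  Pooling the metabolic networks of many species into one
**union network** and tagging every reaction with its **organism degree**
(OD — the number of organisms whose metabolism contains it) turns questions
about metabolic evolution into questions about network structure:

* Do widely shared (high-OD) reactions sit at the centre of the network
  while species-specific reactions sit at the periphery?
* Do reactions with the same OD cluster together, as they would if groups of
  reactions were gained and lost as units (e.g. by horizontal gene
  transfer)?
* Is there a connected, omnipresent metabolic core?
* How much of this structure arises from biochemical adjacency constraints
  alone, with no selection — i.e. from a neutral growth process on the
  universe of known reactions?

`odnet` implements the full analysis chain for these questions, plus a
synthetic-data generator that produces reaction universes and
phylogenetically correlated organism reaction sets with known ground truth,
so every stage can be validated end to end.

## Methods in brief

* **Build** — a bipartite metabolite/reaction graph is read from a TSV
  reaction table; metabolites with bipartite connectivity strictly greater
  than a threshold (default 10) are pruned as currency metabolites (water,
  ATP, ...); the remainder is projected to a directed reaction–reaction
  network with an edge r1 → r2 whenever a product of r1 is a substrate of
  r2; OD is attached from the per-reaction organism sets.
* **Coarse-grain** — connected reactions in the same OD bin (bin width ΔOD,
  default 1) collapse into *super nodes*.  Clustering strength is scored
  against an OD-reshuffling null via

  &nbsp;&nbsp;&nbsp;&nbsp;Z = (s̄ − μ_rand) / σ_rand,

  where s̄ is the observed mean super-node size and μ_rand, σ_rand are the
  mean and standard deviation of that statistic over reshuffled replicates
  (default 20).  The *metabolic core* is the largest super node of maximum
  OD, reported as s_core/N_tot and s_core/N_ODmax.
* **Profile** — the centre is the reaction of highest betweenness centrality
  among those present in all organisms; the mean OD per breadth-first shell
  measures the core→periphery OD gradient, and the two-node correlation
  p_same(k) — the likelihood that two reactions exactly k steps apart share
  an OD — is compared with its reshuffled baseline.
* **Grow** — the neutral model grows a reaction set on a fixed background
  universe: each step adds (probability p, default 1) a uniformly chosen
  reaction adjacent to the current set, or removes (probability 1 − p) a
  uniformly chosen leaf.  An ensemble size-matched to the organisms, pooled
  into a model union, is analysed exactly like real data.

## Worked example

```python
import odnet

ds = odnet.generate_dataset()                 # default study conditions, seed 0
union = odnet.union_network(ds)
print(f"union: {union.n_nodes} reactions, {union.n_edges} links")

zs = odnet.supernode_zscore(union, od_bin_width=1, n_randomizations=20, rng=3)
print(f"s_bar = {zs.mean_size:.3f}, mu = {zs.null_mean:.3f}, "
      f"sigma = {zs.null_sd:.3f}  ->  Z = {zs.z:.1f}")

report = odnet.core_sizes(odnet.coarse_grain(union))
center = odnet.central_node(union)
prof = odnet.od_vs_distance(union, center)
corr = odnet.same_od_correlation(union, max_k=5, n_randomizations=20, rng=4)
```

prints

```
union: 244 reactions, 243 links
s_bar = 1.251, mu = 1.045, sigma = 0.016  ->  Z = 12.6
```

and the remaining objects hold `s_core = 31` (`s_core/N_tot = 0.127`,
`s_core/N_ODmax = 1.00` — the 31 reactions present in all 32 organisms form
one connected core), a shell-mean OD falling from 32 at the centre to 11.1
ten steps out (global mean 15.2), and `p_same(1) = 0.202` against a
reshuffled baseline of 0.049.  Interpretation: same-OD reactions cluster far
beyond chance (Z ≈ 13), and OD decays from core to periphery — exactly the
structure the tree-shaped gain/loss generator plants.

The same pipeline runs from the shell:

```
odnet simulate-data --n-organisms 32 --seed 0 --out data/
odnet run --table data/union_reactions.tsv --with-growth --seed 0 --out results/
odnet compare results/report.json other/report.json
```

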