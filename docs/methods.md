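# Methods

This note records the models, conventions and numerical choices behind
`odnet`, in the order the pipeline applies them.

## Network construction

A metabolism is a bipartite graph: metabolite → reaction links for
substrates, reaction → metabolite links for products.  Reversibility is not
modelled; a reversible reaction must be encoded as one reaction-table row in
its canonical direction.  Reaction ids are primary keys — deduplication of
multifunctional enzymes is upstream identity resolution and out of scope.

**Currency-metabolite pruning.** A metabolite's *connectivity* is its total
bipartite degree, substrate links plus product links, because currency
compounds (water, ATP, NADH) are both heavily consumed and heavily
produced.  A metabolite is pruned when its connectivity is *strictly
greater* than the threshold (default 10): a metabolite of degree exactly 10
survives.  Pruning precedes projection, and reactions are never removed.

**Projection.** The reaction–reaction network has a directed edge r1 → r2
iff some surviving metabolite is a product of r1 and a substrate of r2.
Self-loops (a reaction consuming its own product) are discarded and parallel
edges collapsed: all downstream statistics are defined on simple graphs.

**Organism degree.** od(r) = number of organisms whose reaction set contains
r.  The consistency diagnostic asks, over adjacent (undirected) pairs with
equal OD, how often the two organism *sets* are identical — a high fraction
justifies compressing the phylogenetic profile into the single OD number.
With no same-OD adjacent pairs the fraction is reported as 1.0 (vacuous).

## Coarse-graining and the reshuffling null

Super nodes are the connected components — on the *undirected* view, since
the clustering notion never invokes direction — of each OD bin's induced
subgraph, found by an iterative depth-first search.  Bins are anchored at 1
with fixed boundaries (1..ΔOD, ΔOD+1..2ΔOD, ...); ΔOD = 1 means exact OD
equality, while 10 or 50 compensates for OD sparseness in large unions.  Two
super nodes are joined when at least one reaction in each is linked to the
other; by construction no two adjacent super nodes share a bin.  No super
node is ever dropped from computed statistics.

The null model reshuffles OD values uniformly over the fixed topology
(membership is dropped, as a permuted OD corresponds to no species list) and
recomputes the partition from scratch per replicate.  The z-score
standardises the observed mean super-node size s̄ by the mean and *sample*
standard deviation (ddof = 1; the replicate count is small) of the replicate
means.  The default of 20 replicates is configurable and the seed is
recorded in the result.  A zero-variance null (e.g. all ODs equal) is a
reported error, not a z-score.  The normal-tail p-value conventionally
quoted next to large Z values is not recomputed from replicates.

The core-size report takes the *top occupied* OD bin, with s_core the
largest super-node size in it and N_ODmax the bin's total reaction count.
ΔOD must be stated with every report since it changes what "the core" means.

## Centre and profiles

Betweenness centrality is computed unnormalized with endpoints excluded, on
the undirected view.  The centre is the highest-betweenness node *among
maximum-OD reactions* (present in the most organisms); ties break to the
lexicographically smallest id, and the unconditioned argmax is logged for
comparison when the two differ.  When maximum-OD nodes and the betweenness
argmax disagree, the conditioned rule always wins: the centre is meant to be
an ancestral, universally shared reaction, not merely a topological hub.

The OD–distance profile averages od over breadth-first shells from the
centre; nodes in other components are counted as unreachable and excluded.
The correlation function p_same(k) is the fraction of *unordered* node pairs
at undirected shortest-path distance exactly k with equal OD (equal bins
when a bin width is given; exact equality is the default).  Pairs in
different components have no distance and never enter.  A k with no pairs is
omitted rather than reported as 0.  The baseline permutes the OD vector over
the fixed topology; since distances are unchanged, pair buckets are computed
once and only equality counts are redone per replicate — the expectation is
Σ_o n_o(n_o−1)/(N(N−1)), flat in k.

## Neutral growth model

The background universe is the projected (and identically pruned) reaction
universe restricted to its giant weakly connected component.  Growth state
is a reaction set; per step, with probability p a uniformly chosen *frontier*
reaction (not in the set, adjacent to it in the undirected background) is
added, else a uniformly chosen *leaf* (exactly one link in the induced
subgraph, counting in+out) is removed.  Removing a leaf cannot disconnect
the set.  The seed reaction is protected from removal so a run can always
regrow; with the default p = 1 removal never occurs and a run makes exactly
target_size − 1 additions.  Exhausting the frontier before the target size
is an explicit stalled-growth error (silent truncation would break
size-matching); inside an ensemble the stalled run is kept as a partial
result and the ensemble continues.

Ensembles draw per-run RNG streams from a spawned master seed, so any run is
independently replayable.  Fixed-seed mode reuses one caller-named seed
reaction — the documented recipe picks a maximum-OD reaction, mirroring a
reaction present in every organism — while random mode draws a fresh uniform
background reaction per run.  The model union treats each run as one
organism: od(r) = number of runs containing r, edges restricted from the
background, directly consumable by all analysis stages.

Deliberately out of scope, matching the model's purpose as a minimal
adjacency-constrained ensemble: substrate-availability checks before
addition, chunk-wise gain/loss of reaction groups, and p < 1 production
workflows (supported but not the default).

## Synthetic data generator

No public generative model exists for multi-organism reaction annotations,
so the generator plants the two regularities the analysis measures — an OD
gradient away from an ancestral core, and same-OD clustering — with known
ground truth:

* **Universe.** Reactions are laid down sequentially; each consumes one
  previously produced metabolite (the most recent unconsumed chain tip with
  probability `chain_bias`, else a uniform earlier product) and produces
  1 + Poisson(mean_out_degree − 1) metabolites, fresh until the metabolite
  budget is spent, reused after.  This yields the chain-like topology of
  pruned metabolic pathways, whose mean in/out degree is only slightly above
  one, and guarantees a weakly connected projection.  Defaults: 500
  reactions, 650 metabolites, mean out-degree 1.2, chain bias 0.8 — sized so
  the whole pipeline (including nulls and ensembles) runs in seconds while
  leaving >20 breadth-first shells for gradient estimation.
* **Phylogeny.** Random binary topologies come from sequential uniform
  pairwise joins; branch lengths default to 1 (a coalescent-style
  exponential option exists).  User Newick trees are passed through with
  missing lengths filled with 1.
* **Gain/loss.** The root genome grows by uniform connected accretion from
  the lexicographically smallest reaction.  Along each branch,
  Poisson(gain_rate·L) gains and Poisson(loss_rate·L) losses are applied in
  random interleaved order; a gain adds a uniform frontier neighbour (a
  counted no-op if the frontier is empty), a loss removes a uniform leaf of
  the current set, so every organism's set stays connected — mirroring
  periphery-attached reaction gain.  Defaults: 32 organisms, root genome 30,
  gain 20 and loss 5 per unit branch — rates that give organisms on the
  order of 100 reactions, comparable overlap between related organisms, and
  visible OD structure without saturating the universe.

What the generator does *not* emulate: real stoichiometry, reversibility,
compartments, currency-metabolite hubs (the synthetic universe needs no
pruning, though the pipeline still applies it), horizontal transfer of
multi-reaction chunks, or annotation noise.  Passing tests therefore
demonstrate that the statistics recover planted structure of this kind, not
that any particular biological dataset will show it.

All randomness in a dataset flows through one seeded generator; identical
parameters and seed give byte-identical serialized datasets.  The pipeline
fans a single master seed out to named per-stage streams (universe,
phylogeny, z-score, correlation, growth, model statistics) so stages can be
re-run in isolation; the output directory is excluded from the provenance
echo so reports are byte-identical wherever they are written.

## Numerical and design notes

* Uniform choices from sets are made over sorted elements, making every
  stochastic routine deterministic given its generator state regardless of
  Python hash randomisation.
* Super-node DFS and the union-find used in tests are deliberately distinct
  algorithms for the same partition; likewise the projection has a
  boolean-matrix oracle and betweenness a path-counting oracle.
* Organism sizes for the growth ensemble are taken from the input organism
  reaction sets as given; whether those were counted before or after pruning
  is the caller's choice at the interface.
* The phylogenetic-signal property (sisters more similar than cross-root
  pairs) is tested on a branchy generated universe: on a pure chain the
  frontier never exceeds two reactions, so clades cannot diverge and the
  signal is weak by construction — the chain case is kept as a mean-level
  check only.

## Limitations

OD compresses the full phylogenetic profile to one integer; the consistency
fraction quantifies, per dataset, how much that loses.  The z-score assumes
the replicate means are summarised adequately by two moments; with few
replicates the implied normal tail is an approximation.  Betweenness and
distance statistics treat the union as a static simple graph — fluxes,
stoichiometry and reaction reversibility are outside the model.  The growth
model is neutral by design and is a baseline, not a fitted model of any
specific lineage.
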