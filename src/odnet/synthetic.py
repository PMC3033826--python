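"""Synthetic reaction universes and phylogenetically correlated organisms.

Real inputs for this kind of analysis are curated reaction databases plus
per-organism reaction annotations.  This module generates stand-ins with the
two statistical regularities the downstream analysis measures:

* a near-chain-like directed reaction universe — after currency-metabolite
  pruning, metabolic pathways resemble linear chains whose mean in/out degree
  is only slightly above one;
* organism reaction sets produced by connected gain/loss along a phylogeny,
  so that organism degree (OD) decays away from the ancestral core and
  same-OD reactions cluster.

All randomness flows through one seeded :class:`numpy.random.Generator` per
dataset, making every generated object reproducible byte-for-byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import FixtureLookupError, FormatError, ParameterError
from .network import (
    BipartiteMetabolicNetwork,
    ReactionNetwork,
    project_to_reactions,
    write_reaction_table,
)


@dataclass(frozen=True)
class UniverseParams:
    """Parameters of the background reaction universe.

    ``mean_out_degree`` is the target mean number of products per reaction
    (slightly above one for chain-like metabolism); ``chain_bias`` is the
    probability that a new reaction extends the most recent open chain tip
    rather than branching off a uniformly chosen earlier product.
    """

    n_reactions: int = 500
    n_metabolites: int = 650
    mean_out_degree: float = 1.2
    chain_bias: float = 0.8
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_reactions < 2:
            raise ParameterError("n_reactions must be >= 2")
        if self.n_metabolites < 2:
            raise ParameterError("n_metabolites must be >= 2")
        if self.mean_out_degree <= 0:
            raise ParameterError("mean_out_degree must be > 0")
        if not 0.0 <= self.chain_bias <= 1.0:
            raise ParameterError("chain_bias must lie in [0, 1]")


@dataclass(frozen=True)
class PhylogenySpec:
    """Parameters of the organism phylogeny and the gain/loss process.

    Rates are expected events per unit branch length.  ``tree_newick`` may be
    the literal string ``"random"`` (a random binary topology is drawn) or a
    user-supplied Newick string; missing branch lengths default to 1.
    ``branch_lengths`` selects unit-length branches or exponential
    coalescent-style lengths for random trees.
    """

    n_organisms: int = 32
    tree_newick: str = "random"
    root_genome_size: int = 30
    gain_rate: float = 20.0
    loss_rate: float = 5.0
    rng_seed: int = 0
    branch_lengths: str = "unit"  # "unit" | "coalescent"

    def validate(self) -> None:
        if self.n_organisms < 2:
            raise ParameterError("n_organisms must be >= 2")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ParameterError("rates must be >= 0")
        if self.root_genome_size < 1:
            raise ParameterError("root_genome_size must be >= 1")
        if self.branch_lengths not in ("unit", "coalescent"):
            raise ParameterError("branch_lengths must be 'unit' or 'coalescent'")


@dataclass
class SyntheticDataset:
    """A generated universe, organism reaction sets and the generating tree."""

    universe: BipartiteMetabolicNetwork
    organism_sets: dict[str, frozenset[str]]
    tree: str
    root_genome: frozenset[str] = frozenset()
    gain_noop_count: int = 0

    def validate(self) -> None:
        proj = project_to_reactions(self.universe)
        adj = proj.undirected_adjacency()
        for org, rset in self.organism_sets.items():
            unknown = set(rset) - self.universe.reactions
            if unknown:
                raise FormatError(f"{org}: reactions outside universe: {unknown}")
            if not _is_connected(rset, adj):
                raise FormatError(f"{org}: reaction set not connected in projection")

    def union_membership(self) -> dict[str, frozenset[str]]:
        """Map reaction -> organisms carrying it (reactions in >=1 organism)."""
        out: dict[str, set[str]] = {}
        for org, rset in self.organism_sets.items():
            for r in rset:
                out.setdefault(r, set()).add(org)
        return {r: frozenset(orgs) for r, orgs in out.items()}

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write union reaction table, background table and Newick tree.

        The union table carries organism membership and round-trips through
        :func:`odnet.network.read_reaction_table`; the background table keeps
        every universe reaction with an empty organism field.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        membership = self.union_membership()
        union_bip = BipartiteMetabolicNetwork(
            metabolites=set(self.universe.metabolites),
            reactions=set(membership),
            substrate_links={
                (m, r) for m, r in self.universe.substrate_links if r in membership
            },
            product_links={
                (r, m) for r, m in self.universe.product_links if r in membership
            },
            membership=membership,
        )
        paths = {
            "union": directory / "union_reactions.tsv",
            "background": directory / "background_reactions.tsv",
            "tree": directory / "tree.nwk",
        }
        write_reaction_table(union_bip, paths["union"])
        write_reaction_table(self.universe, paths["background"])
        paths["tree"].write_text(self.tree + "\n")
        return paths


def _is_connected(nodes: frozenset[str] | set[str], adj: dict[str, set[str]]) -> bool:
    if not nodes:
        return True
    nodes = set(nodes)
    start = next(iter(sorted(nodes)))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj.get(v, ()):
            if u in nodes and u not in seen:
                seen.add(u)
                stack.append(u)
    return seen == nodes


def generate_universe(params: UniverseParams) -> BipartiteMetabolicNetwork:
    """Grow a connected, chain-biased directed reaction universe.

    Reactions are laid down sequentially.  Each consumes one previously
    produced metabolite — the most recent unconsumed chain tip with
    probability ``chain_bias``, otherwise a uniformly chosen earlier product —
    and produces ``1 + Poisson(mean_out_degree - 1)`` metabolites (a Bernoulli
    draw below mean 1).  Fresh product metabolites are created until the
    ``n_metabolites`` budget is spent, after which products are reused
    uniformly.  Because every reaction after the first consumes some earlier
    product, the reaction-reaction projection is weakly connected.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    net = BipartiteMetabolicNetwork()

    def new_metabolite() -> str:
        mid = f"m{len(net.metabolites):05d}"
        net.metabolites.add(mid)
        return mid

    source = new_metabolite()
    produced: list[str] = []  # all metabolites produced by some reaction
    tips: list[str] = []  # produced but not yet consumed (stack)
    mu = params.mean_out_degree

    for i in range(params.n_reactions):
        rid = f"r{i:05d}"
        net.reactions.add(rid)
        if i == 0:
            sub = source
        elif tips and rng.random() < params.chain_bias:
            sub = tips.pop()
        else:
            sub = produced[int(rng.integers(len(produced)))]
            if sub in tips:
                tips.remove(sub)
        net.substrate_links.add((sub, rid))

        if mu >= 1.0:
            n_prod = 1 + int(rng.poisson(mu - 1.0))
        else:
            n_prod = int(rng.random() < mu)
        if i == 0:
            n_prod = max(1, n_prod)  # keep the universe rooted in one chain
        prods: set[str] = set()
        for _ in range(n_prod):
            if len(net.metabolites) < params.n_metabolites:
                m = new_metabolite()
            else:
                pool = sorted(net.metabolites - {sub} - prods)
                if not pool:
                    continue
                m = pool[int(rng.integers(len(pool)))]
            prods.add(m)
        for m in sorted(prods):
            net.product_links.add((rid, m))
            produced.append(m)
            tips.append(m)
    return net


def _random_binary_newick(n: int, rng: np.random.Generator, coalescent: bool) -> str:
    """Random binary topology by sequential pairwise joins of lineages."""
    labels = [f"O{i:03d}" for i in range(n)]
    lineages = list(labels)
    k = len(lineages)
    while k > 1:
        i, j = sorted(rng.choice(k, size=2, replace=False))
        length = float(rng.exponential(1.0 / k)) + 1e-6 if coalescent else 1.0
        merged = f"({lineages[i]}:{length:.6g},{lineages[j]}:{length:.6g})"
        lineages[i] = merged
        lineages.pop(j)
        k -= 1
    return lineages[0] + ";"


def generate_phylogeny(spec: PhylogenySpec) -> str:
    """Return a binary Newick tree with positive branch lengths.

    A random topology is drawn when ``tree_newick == "random"``; a
    user-supplied Newick string is validated and passed through with missing
    branch lengths filled in with 1.
    """
    spec.validate()
    if spec.tree_newick == "random":
        rng = np.random.default_rng(spec.rng_seed)
        return _random_binary_newick(
            spec.n_organisms, rng, spec.branch_lengths == "coalescent"
        )
    try:
        tree = dendropy.Tree.get(
            data=spec.tree_newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = 1.0
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


def _grow_connected(
    adj: dict[str, set[str]],
    seed: str,
    size: int,
    rng: np.random.Generator,
) -> set[str]:
    """Uniform frontier-neighbour accretion, as in the neutral growth model."""
    current = {seed}
    frontier = set(adj[seed])
    while len(current) < size:
        if not frontier:
            raise ParameterError(
                f"cannot grow a connected set of size {size} from {seed!r}; "
                f"stalled at {len(current)}"
            )
        pool = sorted(frontier)
        pick = pool[int(rng.integers(len(pool)))]
        current.add(pick)
        frontier.discard(pick)
        frontier |= adj[pick] - current
    return current


def evolve_organisms(
    universe: BipartiteMetabolicNetwork, spec: PhylogenySpec
) -> SyntheticDataset:
    """Evolve organism reaction sets along a phylogeny by connected gain/loss.

    The root genome is grown by uniform connected accretion from the
    lexicographically smallest reaction of the projected universe.  Along each
    branch of length L, ``Poisson(gain_rate * L)`` gains and
    ``Poisson(loss_rate * L)`` losses are applied in random interleaved order:
    a gain adds a uniformly chosen frontier neighbour (a gain with an empty
    frontier is a counted no-op), a loss removes a uniformly chosen leaf
    (induced degree 1) of the current set — leaf removal can never disconnect
    it, and a single-reaction genome loses nothing.  Every leaf organism's
    set is therefore a connected subgraph of the projected universe.
    """
    spec.validate()
    proj = project_to_reactions(universe)
    if spec.root_genome_size > len(proj.nodes):
        raise ParameterError("root_genome_size exceeds the universe size")
    rng = np.random.default_rng(spec.rng_seed)
    adj = proj.undirected_adjacency()
    newick = (
        generate_phylogeny(spec) if spec.tree_newick == "random" else spec.tree_newick
    )
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    root_seed = min(proj.nodes)
    root_genome = _grow_connected(adj, root_seed, spec.root_genome_size, rng)

    noops = 0
    genomes: dict[int, set[str]] = {id(tree.seed_node): set(root_genome)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        genome = set(genomes[id(node.parent_node)])
        length = node.edge.length if node.edge.length is not None else 1.0
        n_gain = int(rng.poisson(spec.gain_rate * length))
        n_loss = int(rng.poisson(spec.loss_rate * length))
        events = ["g"] * n_gain + ["l"] * n_loss
        rng.shuffle(events)
        for ev in events:
            if ev == "g":
                frontier = sorted(
                    {u for v in genome for u in adj[v]} - genome
                )
                if not frontier:
                    noops += 1
                    continue
                genome.add(frontier[int(rng.integers(len(frontier)))])
            else:
                if len(genome) <= 1:
                    continue
                leaves = sorted(
                    v for v in genome if len(adj[v] & genome) <= 1
                )
                if not leaves:
                    continue
                genome.discard(leaves[int(rng.integers(len(leaves)))])
        genomes[id(node)] = genome

    organism_sets = {
        leaf.taxon.label: frozenset(genomes[id(leaf)])
        for leaf in tree.leaf_node_iter()
    }
    return SyntheticDataset(
        universe=universe,
        organism_sets=organism_sets,
        tree=newick,
        root_genome=frozenset(root_genome),
        gain_noop_count=noops,
    )


def generate_dataset(
    universe_params: UniverseParams | None = None,
    phylogeny_spec: PhylogenySpec | None = None,
) -> SyntheticDataset:
    """Convenience: universe + phylogeny + gain/loss in one call."""
    universe_params = universe_params or UniverseParams()
    phylogeny_spec = phylogeny_spec or PhylogenySpec()
    universe = generate_universe(universe_params)
    return evolve_organisms(universe, phylogeny_spec)


def _chain_universe(n: int) -> BipartiteMetabolicNetwork:
    """r0 -> r1 -> ... -> r(n-1) through metabolites m0..mn."""
    net = BipartiteMetabolicNetwork()
    for i in range(n):
        rid = f"r{i}"
        net.reactions.add(rid)
        net.metabolites.update({f"m{i}", f"m{i + 1}"})
        net.substrate_links.add((f"m{i}", rid))
        net.product_links.add((rid, f"m{i + 1}"))
    return net


def _fixture_chain4() -> SyntheticDataset:
    """4-reaction chain, 2 organisms, ODs [2, 2, 1, 1] along the chain."""
    net = _chain_universe(4)
    sets = {
        "orgA": frozenset({"r0", "r1"}),
        "orgB": frozenset({"r0", "r1", "r2", "r3"}),
    }
    return SyntheticDataset(universe=net, organism_sets=sets, tree="(orgA:1,orgB:1);")


def _fixture_star() -> SyntheticDataset:
    """Hub present in all 5 organisms (OD 5); leaves with ODs 1, 2 and 3."""
    net = BipartiteMetabolicNetwork()
    net.reactions = {"hub", "leaf1", "leaf2", "leaf3"}
    net.metabolites = {"m0", "ma", "mb", "mc"}
    net.substrate_links = {("m0", "hub"), ("ma", "leaf1"), ("mb", "leaf2"), ("mc", "leaf3")}
    net.product_links = {("hub", "ma"), ("hub", "mb"), ("hub", "mc")}
    sets = {
        "org1": frozenset({"hub", "leaf1", "leaf2", "leaf3"}),
        "org2": frozenset({"hub", "leaf2", "leaf3"}),
        "org3": frozenset({"hub", "leaf3"}),
        "org4": frozenset({"hub"}),
        "org5": frozenset({"hub"}),
    }
    tree = "((org1:1,org2:1):1,(org3:1,(org4:1,org5:1):1):1);"
    return SyntheticDataset(universe=net, organism_sets=sets, tree=tree)


def _fixture_twocore() -> SyntheticDataset:
    """Two OD-2 clusters of size 3 bridged by a single OD-1 reaction.

    Coarse-graining at bin width 1 yields super nodes of sizes [3, 1, 3];
    the bridge keeps the two same-OD clusters from merging.
    """
    net = _chain_universe(7)  # chain r0..r6; r3 is the bridge
    sets = {
        "orgW": frozenset({"r0", "r1", "r2", "r3", "r4", "r5", "r6"}),
        "orgX": frozenset({"r0", "r1", "r2"}),
        "orgY": frozenset({"r4", "r5", "r6"}),
    }
    tree = "(orgW:1,(orgX:1,orgY:1):1);"
    return SyntheticDataset(universe=net, organism_sets=sets, tree=tree)


_FIXTURES = {
    "chain4": _fixture_chain4,
    "star": _fixture_star,
    "twocore": _fixture_twocore,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def toy_fixture(name: str) -> SyntheticDataset:
    """Return a hard-coded small dataset with hand-checkable statistics."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        ) from None
    return builder()


def union_network(dataset: SyntheticDataset) -> ReactionNetwork:
    """Project the (unpruned) universe and build the OD-tagged union."""
    from .network import build_union

    proj = project_to_reactions(dataset.universe)
    return build_union(dataset.organism_sets, proj)
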