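"""Synthetic universes, phylogenies and gain/loss organism evolution."""

import dataclasses

import dendropy
import numpy as np
import pytest
from scipy import stats

from odnet.errors import FixtureLookupError, FormatError, ParameterError
from odnet.network import project_to_reactions
from odnet.synthetic import (
    PhylogenySpec,
    UniverseParams,
    _chain_universe,
    evolve_organisms,
    generate_phylogeny,
    generate_universe,
    toy_fixture,
    union_network,
)


def bfs_components(nodes, edges):
    """Independent component sweep (undirected) for the giant-component check."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            v = queue.pop()
            for u in adj[v]:
                if u not in comp:
                    comp.add(u)
                    queue.append(u)
        seen |= comp
        comps.append(comp)
    return comps


class TestUniverse:
    def test_deterministic_given_seed(self):
        p = UniverseParams(n_reactions=500, n_metabolites=600, rng_seed=1)
        a, b = generate_universe(p), generate_universe(p)
        assert a.substrate_links == b.substrate_links
        assert a.product_links == b.product_links

    def test_giant_component_and_out_degree(self):
        p = UniverseParams(n_reactions=500, rng_seed=1)
        uni = generate_universe(p)
        proj = project_to_reactions(uni)
        comps = bfs_components(proj.nodes, proj.edges)
        assert max(len(c) for c in comps) / len(proj.nodes) >= 0.9
        mean_out = np.mean([len(uni.products_of(r)) for r in uni.reactions])
        assert abs(mean_out - p.mean_out_degree) / p.mean_out_degree <= 0.2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_reactions": 1},
            {"n_metabolites": 1},
            {"mean_out_degree": 0.0},
            {"chain_bias": 1.5},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            generate_universe(UniverseParams(**kwargs))


class TestPhylogeny:
    @pytest.mark.parametrize("n", [2, 7, 20])
    def test_binary_tree_shape(self, n):
        nwk = generate_phylogeny(PhylogenySpec(n_organisms=n, rng_seed=3))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = tree.leaf_nodes()
        internal = [v for v in tree if not v.is_leaf()]
        assert len(leaves) == n
        assert len(internal) == n - 1  # binary-tree identity
        assert all(e.length > 0 for e in tree.preorder_edge_iter()
                   if e.head_node is not tree.seed_node)

    def test_deterministic_given_seed(self):
        spec = PhylogenySpec(n_organisms=9, rng_seed=5)
        assert generate_phylogeny(spec) == generate_phylogeny(spec)

    def test_user_newick_passthrough_with_default_lengths(self):
        nwk = generate_phylogeny(
            PhylogenySpec(n_organisms=3, tree_newick="((A,B),C);")
        )
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_nodes()) == ["A", "B", "C"]
        assert all(e.length == 1.0 for e in tree.preorder_edge_iter()
                   if e.head_node is not tree.seed_node)

    def test_malformed_newick(self):
        with pytest.raises(FormatError):
            generate_phylogeny(PhylogenySpec(n_organisms=2, tree_newick="((A,B;"))


class TestEvolution:
    def toy_spec(self, **kw):
        base = dict(
            n_organisms=4,
            tree_newick="((A:1,B:1):1,(C:1,D:1):1);",
            root_genome_size=3,
            gain_rate=2.0,
            loss_rate=1.0,
            rng_seed=7,
        )
        base.update(kw)
        return PhylogenySpec(**base)

    def test_zero_rates_copy_root_everywhere(self):
        uni = _chain_universe(6)
        ds = evolve_organisms(uni, self.toy_spec(gain_rate=0.0, loss_rate=0.0))
        assert len({s for s in ds.organism_sets.values()}) == 1
        union = union_network(ds)
        assert set(union.od.values()) == {4}

    def test_pure_gain_keeps_root_genome(self):
        uni = _chain_universe(6)
        ds = evolve_organisms(uni, self.toy_spec(loss_rate=0.0, gain_rate=3.0))
        for rset in ds.organism_sets.values():
            assert ds.root_genome <= rset

    def test_organism_sets_connected(self):
        uni = generate_universe(UniverseParams(n_reactions=200, n_metabolites=260, rng_seed=3))
        ds = evolve_organisms(
            uni, PhylogenySpec(n_organisms=8, root_genome_size=15, rng_seed=3)
        )
        ds.validate()  # raises if any organism set is disconnected

    @staticmethod
    def _sister_minus_cross(uni, seeds, **spec_kw):
        def jac(a, b):
            return len(a & b) / len(a | b)

        diffs = []
        for seed in seeds:
            ds = evolve_organisms(
                uni,
                PhylogenySpec(
                    n_organisms=4, tree_newick="((A:1,B:1):1,(C:1,D:1):1);",
                    rng_seed=seed, **spec_kw,
                ),
            )
            s = ds.organism_sets
            sisters = (jac(s["A"], s["B"]) + jac(s["C"], s["D"])) / 2
            cross = np.mean([jac(s[x], s[y]) for x in "AB" for y in "CD"])
            diffs.append(sisters - cross)
        return np.array(diffs)

    def test_sister_similarity_on_toy_chain(self):
        """On a 6-reaction chain, sister Jaccard >= cross-pair Jaccard on average."""
        diffs = self._sister_minus_cross(
            _chain_universe(6), range(200),
            root_genome_size=2, gain_rate=1.0, loss_rate=0.5,
        )
        assert diffs.mean() >= 0

    def test_phylogenetic_signal_sign_test(self):
        """Sister pairs beat cross-root pairs over 100 seeds (sign test p < 0.01)."""
        uni = generate_universe(
            UniverseParams(n_reactions=150, n_metabolites=200, rng_seed=1)
        )
        diffs = self._sister_minus_cross(
            uni, range(100), root_genome_size=10, gain_rate=8.0, loss_rate=2.0,
        )
        n_pos, n_nonzero = int((diffs > 0).sum()), int((diffs != 0).sum())
        p = stats.binomtest(n_pos, n_nonzero, alternative="greater").pvalue
        assert p < 0.01

    def test_planted_gradient_peaks_on_root_genome(self):
        uni = generate_universe(UniverseParams(n_reactions=300, n_metabolites=400, rng_seed=5))
        ds = evolve_organisms(
            uni,
            PhylogenySpec(n_organisms=8, root_genome_size=20, gain_rate=10.0,
                          loss_rate=0.0, rng_seed=5),
        )
        union = union_network(ds)
        root_ods = [union.od[r] for r in ds.root_genome]
        other = [union.od[r] for r in union.nodes - ds.root_genome]
        assert min(root_ods) == max(union.od.values())
        assert np.mean(root_ods) >= np.mean(other)

    def test_deterministic_dataset_serialization(self, tmp_path):
        uni = generate_universe(UniverseParams(n_reactions=100, n_metabolites=140, rng_seed=2))
        spec = PhylogenySpec(n_organisms=5, root_genome_size=10, rng_seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        evolve_organisms(uni, spec).write(d1)
        evolve_organisms(uni, spec).write(d2)
        for name in ("union_reactions.tsv", "background_reactions.tsv", "tree.nwk"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestFixtures:
    def test_documented_fixture_statistics(self, chain4_union, star_union, twocore_union):
        assert sorted(chain4_union.od.values()) == [1, 1, 2, 2]
        assert star_union.od["hub"] == 5
        assert sorted(star_union.od[x] for x in ("leaf1", "leaf2", "leaf3")) == [1, 2, 3]
        assert sorted(twocore_union.od.values()) == [1, 2, 2, 2, 2, 2, 2]

    def test_fixtures_are_valid_datasets(self):
        for name in ("chain4", "star", "twocore"):
            toy_fixture(name).validate()

    def test_unknown_name(self):
        with pytest.raises(FixtureLookupError):
            toy_fixture("nope")
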