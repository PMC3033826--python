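"""Bipartite construction, currency-metabolite pruning and projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odnet.errors import FormatError, MembershipError
from odnet.network import (
    BipartiteMetabolicNetwork,
    ReactionNetwork,
    build_union,
    od_species_consistency,
    project_to_reactions,
    prune_currency_metabolites,
    read_reaction_table,
    write_reaction_table,
)
from odnet.synthetic import UniverseParams, generate_universe

from conftest import random_bipartite


def brute_force_projection_edges(net: BipartiteMetabolicNetwork) -> set:
    """O(R^2) oracle: check every ordered reaction pair for a shared metabolite."""
    edges = set()
    prods = {r: net.products_of(r) for r in net.reactions}
    subs = {r: net.substrates_of(r) for r in net.reactions}
    for r1 in net.reactions:
        for r2 in net.reactions:
            if r1 != r2 and prods[r1] & subs[r2]:
                edges.add((r1, r2))
    return edges


class TestReactionTable:
    def test_single_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "reaction_id\tsubstrates\tproducts\torganisms\n"
            "r1\tm1\tm2\torgA;orgB\n"
        )
        net = read_reaction_table(p)
        assert net.reactions == {"r1"}
        assert net.metabolites == {"m1", "m2"}
        assert net.membership == {"r1": frozenset({"orgA", "orgB"})}

    @pytest.mark.parametrize(
        "body, message",
        [
            ("r1\tm1\tm2\torgA\nr1\tm2\tm3\torgB\n", "duplicate"),
            ("r1\tm1\tm2\t\n", "empty organism"),
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, body, message):
        p = tmp_path / "t.tsv"
        p.write_text("reaction_id\tsubstrates\tproducts\torganisms\n" + body)
        with pytest.raises(FormatError, match=message):
            read_reaction_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("reaction_id\tsubstrates\tproducts\nr1\tm1\tm2\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_reaction_table(p)

    def test_round_trip_of_synthetic_universe(self, tmp_path):
        uni = generate_universe(UniverseParams(rng_seed=4))
        uni.membership = {r: frozenset({"orgA"}) for r in uni.reactions}
        p = tmp_path / "u.tsv"
        write_reaction_table(uni, p)
        back = read_reaction_table(p)
        assert back.reactions == uni.reactions
        assert back.metabolites == uni.metabolites
        assert back.substrate_links == uni.substrate_links
        assert back.product_links == uni.product_links
        assert back.membership == uni.membership


class TestPruning:
    def test_strictly_greater_than_threshold(self):
        net = BipartiteMetabolicNetwork()
        net.metabolites = {"atp", "mx"}
        net.reactions = {f"r{i}" for i in range(12)}
        net.substrate_links = {("atp", f"r{i}") for i in range(12)}
        net.substrate_links |= {("mx", f"r{i}") for i in range(10)}
        pruned = prune_currency_metabolites(net, threshold=10)
        assert "atp" not in pruned.metabolites  # degree 12 > 10
        assert "mx" in pruned.metabolites  # degree exactly 10 survives
        assert pruned.reactions == net.reactions

    def test_pure_function(self):
        net = BipartiteMetabolicNetwork()
        net.metabolites, net.reactions = {"m"}, {"r"}
        net.substrate_links = {("m", "r")}
        out = prune_currency_metabolites(net, 10)
        out.metabolites.discard("m")
        assert "m" in net.metabolites

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 15), st.integers(1, 15))
    def test_monotone_in_threshold(self, seed, t_low, t_high):
        """A higher threshold never removes more metabolites."""
        t_low, t_high = sorted((t_low, t_high))
        net = random_bipartite(np.random.default_rng(seed), max_reactions=40)
        removed_high = net.metabolites - prune_currency_metabolites(net, t_high).metabolites
        removed_low = net.metabolites - prune_currency_metabolites(net, t_low).metabolites
        assert removed_high <= removed_low
        # fewer surviving metabolites can only reduce projected edges
        e_low = project_to_reactions(prune_currency_metabolites(net, t_low)).edges
        e_high = project_to_reactions(prune_currency_metabolites(net, t_high)).edges
        assert len(e_low) <= len(e_high)


class TestProjection:
    def test_smallest_chain(self):
        net = BipartiteMetabolicNetwork()
        net.metabolites = {"m1", "m2", "m3"}
        net.reactions = {"r1", "r2"}
        net.substrate_links = {("m1", "r1"), ("m2", "r2")}
        net.product_links = {("r1", "m2"), ("r2", "m3")}
        proj = project_to_reactions(net)
        assert proj.edges == {("r1", "r2")}

    def test_no_self_loop(self):
        net = BipartiteMetabolicNetwork()
        net.metabolites, net.reactions = {"m"}, {"r1"}
        net.substrate_links = {("m", "r1")}
        net.product_links = {("r1", "m")}
        assert project_to_reactions(net).edges == set()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pairwise_enumeration(self, seed):
        net = random_bipartite(np.random.default_rng(seed), max_reactions=60)
        proj = project_to_reactions(net)
        assert proj.edges == brute_force_projection_edges(net)


class TestUnion:
    def test_od_counts_organisms(self):
        proj = ReactionNetwork(
            nodes={"r1", "r2", "r3"}, edges={("r1", "r2"), ("r2", "r3")}
        )
        union = build_union({"A": {"r1", "r2"}, "B": {"r2", "r3"}}, proj)
        assert union.od == {"r1": 1, "r2": 2, "r3": 1}
        assert union.edges == {("r1", "r2"), ("r2", "r3")}

    def test_single_organism_all_od_one(self):
        proj = ReactionNetwork(nodes={"a", "b"}, edges={("a", "b")})
        union = build_union({"A": {"a", "b"}}, proj)
        assert set(union.od.values()) == {1}
        assert union.nodes == proj.nodes and union.edges == proj.edges

    def test_chain4_fixture_ods(self, chain4_union):
        assert chain4_union.od == {"r0": 2, "r1": 2, "r2": 1, "r3": 1}

    def test_unknown_reaction_rejected(self):
        proj = ReactionNetwork(nodes={"a"}, edges=set())
        with pytest.raises(MembershipError):
            build_union({"A": {"a", "zz"}}, proj)

    def test_od_bookkeeping_sum(self):
        """Sum of ODs equals the summed organism reaction-set sizes."""
        rng = np.random.default_rng(11)
        proj = ReactionNetwork(nodes={f"r{i}" for i in range(40)}, edges=set())
        sets = {
            f"O{j}": {f"r{i}" for i in rng.choice(40, size=15, replace=False)}
            for j in range(6)
        }
        union = build_union(sets, proj)
        assert sum(union.od.values()) == sum(len(s) for s in sets.values())


class TestConsistency:
    def test_discordant_pair_counted(self):
        net = ReactionNetwork(
            nodes={"r1", "r2", "r3"},
            edges={("r1", "r3")},
            membership={
                "r1": frozenset({"A"}),
                "r2": frozenset({"A", "B"}),
                "r3": frozenset({"B"}),
            },
        )
        frac, discordant = od_species_consistency(net)
        assert frac == 0.0
        assert discordant == [("r1", "r3")]

    def test_identical_organism_sets_give_one(self):
        net = ReactionNetwork(
            nodes={"a", "b"},
            edges={("a", "b")},
            membership={"a": frozenset({"X"}), "b": frozenset({"X"})},
        )
        assert od_species_consistency(net)[0] == 1.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        nodes = [f"r{i}" for i in range(50)]
        membership = {
            n: frozenset(f"O{j}" for j in range(8) if rng.random() < 0.4) or frozenset({"O0"})
            for n in nodes
        }
        edges = set()
        for _ in range(120):
            a, b = rng.choice(50, size=2, replace=False)
            edges.add((nodes[a], nodes[b]))
        net = ReactionNetwork(nodes=set(nodes), edges=edges, membership=membership)
        frac, discordant = od_species_consistency(net)
        pairs = {tuple(sorted(e)) for e in edges}
        same = [(a, b) for a, b in pairs if len(membership[a]) == len(membership[b])]
        bad = [(a, b) for a, b in same if membership[a] != membership[b]]
        assert frac == pytest.approx(1 - len(bad) / len(same))
        assert len(discordant) == len(bad)
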