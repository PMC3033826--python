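"""Core-periphery profiles of organism degree.

Two complementary statistics locate where widely shared reactions sit:

* the mean organism degree (OD) of the reactions found d steps away from the
  most central reaction node — the centre is the node of highest betweenness
  centrality among those present in every organism;
* the two-node correlation function p_same(k): the likelihood that two
  reactions exactly k steps apart carry the same OD, compared with a baseline
  in which ODs are reshuffled over the fixed topology.

All distances and centralities use the undirected view of the reaction
network, and a pair of reactions contributes once (unordered).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import AnnotationError
from .network import ReactionNetwork

logger = logging.getLogger(__name__)


@dataclass
class ODDistanceProfile:
    """Shell-mean OD as a function of distance from the centre node."""

    center: str
    per_distance: list[tuple[int, float, int]]  # (distance, mean od, n nodes)
    global_mean_od: float
    unreachable_count: int

    def distances(self) -> list[int]:
        return [d for d, _, _ in self.per_distance]

    def shell_means(self) -> list[float]:
        return [m for _, m, _ in self.per_distance]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("distance\tmean_od\tn_nodes\n")
            for d, m, n in self.per_distance:
                fh.write(f"{d}\t{m:.6g}\t{n}\n")


@dataclass
class ODCorrelationProfile:
    """p_same(k) with its reshuffled baseline (mean +/- sd over replicates)."""

    per_k: list[tuple[int, float, int]]  # (k, p_same, n_pairs)
    baseline_per_k: list[tuple[int, float, float]]  # (k, mean, sd)
    n_randomizations: int
    rng_seed: int | None = None

    def ks(self) -> list[int]:
        return [k for k, _, _ in self.per_k]

    def write_tsv(self, path: str | Path) -> None:
        base = {k: (m, s) for k, m, s in self.baseline_per_k}
        with open(path, "w") as fh:
            fh.write("k\tp_same\tn_pairs\tbaseline_mean\tbaseline_sd\n")
            for k, p, n in self.per_k:
                m, s = base[k]
                fh.write(f"{k}\t{p:.6g}\t{n}\t{m:.6g}\t{s:.6g}\n")

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_k": self.per_k,
                "baseline_per_k": self.baseline_per_k,
                "n_randomizations": self.n_randomizations,
                "rng_seed": self.rng_seed,
            },
            sort_keys=True,
        )


def betweenness(net: ReactionNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness on the undirected view.

    Endpoints are excluded; on an undirected graph each unordered pair is
    counted once.
    """
    g = net.to_undirected_networkx()
    return dict(nx.betweenness_centrality(g, normalized=False))


def central_node(net: ReactionNetwork) -> str:
    """Most central reaction: highest betweenness among maximum-OD nodes.

    Only reactions whose OD equals the network maximum (i.e. those present
    in the largest number of organisms) are candidates; ties are broken by
    lexicographically smallest id.  The unconditioned betweenness argmax is
    logged for comparison when it differs.
    """
    if not net.nodes:
        raise AnnotationError("empty network has no central node")
    od = net.require_od()
    bc = betweenness(net)
    od_max = max(od.values())
    candidates = sorted(n for n in net.nodes if od[n] == od_max)
    # tie-break: highest betweenness, then lexicographically smallest id
    best_bc = max(bc[n] for n in candidates)
    center = min(n for n in candidates if bc[n] == best_bc)
    overall = min(n for n in net.nodes if bc[n] == max(bc.values()))
    if overall != center:
        logger.info(
            "unconditioned betweenness argmax %s (od=%d) differs from "
            "conditioned centre %s (od=%d)",
            overall, od[overall], center, od[center],
        )
    return center


def od_vs_distance(net: ReactionNetwork, center: str) -> ODDistanceProfile:
    """Breadth-first shells from the centre with per-shell mean OD.

    Nodes unreachable from the centre (other weak components) are excluded
    from the shells and reported in ``unreachable_count``.
    """
    if center not in net.nodes:
        raise AnnotationError(f"center {center!r} not in network")
    od = net.require_od()
    g = net.to_undirected_networkx()
    dist = nx.single_source_shortest_path_length(g, center)
    shells: dict[int, list[int]] = {}
    for n, d in dist.items():
        shells.setdefault(d, []).append(od[n])
    per = [
        (d, float(np.mean(vals)), len(vals)) for d, vals in sorted(shells.items())
    ]
    return ODDistanceProfile(
        center=center,
        per_distance=per,
        global_mean_od=float(np.mean([od[n] for n in net.nodes])),
        unreachable_count=len(net.nodes) - len(dist),
    )


def _pairs_by_distance(
    net: ReactionNetwork, max_k: int
) -> tuple[list[str], dict[int, np.ndarray]]:
    """Unordered node pairs grouped by exact shortest-path distance <= max_k."""
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    g = net.to_undirected_networkx()
    buckets: dict[int, list[tuple[int, int]]] = {k: [] for k in range(1, max_k + 1)}
    for n in nodes:
        i = index[n]
        for m, d in nx.single_source_shortest_path_length(g, n, cutoff=max_k).items():
            j = index[m]
            if j > i and d >= 1:
                buckets[d].append((i, j))
    arrays = {
        k: np.array(v, dtype=np.int64).reshape(-1, 2)
        for k, v in buckets.items()
        if v
    }
    return nodes, arrays


def same_od_correlation(
    net: ReactionNetwork,
    max_k: int = 10,
    n_randomizations: int = 20,
    rng: np.random.Generator | int | None = None,
    od_bin_width: int = 1,
) -> ODCorrelationProfile:
    """Two-node same-OD correlation function with a reshuffling baseline.

    For each k <= max_k, p_same(k) is the fraction of unordered reaction
    pairs at undirected shortest-path distance exactly k whose ODs are equal
    (equal OD bins when ``od_bin_width > 1``).  Distances in different weak
    components are undefined, so such pairs never enter; a k with no pairs is
    omitted.  The baseline permutes the OD values over the fixed topology —
    pair distances are unchanged, so only the equality counts are redone per
    replicate.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    od = net.require_od()
    nodes, buckets = _pairs_by_distance(net, max_k)
    vals = np.array([od[n] for n in nodes])
    if od_bin_width > 1:
        vals = (vals - 1) // od_bin_width

    def p_same(values: np.ndarray, pairs: np.ndarray) -> float:
        return float(np.mean(values[pairs[:, 0]] == values[pairs[:, 1]]))

    per_k = [
        (k, p_same(vals, pairs), len(pairs)) for k, pairs in sorted(buckets.items())
    ]
    base: dict[int, list[float]] = {k: [] for k in buckets}
    for _ in range(n_randomizations):
        perm = vals[rng.permutation(len(vals))]
        for k, pairs in buckets.items():
            base[k].append(p_same(perm, pairs))
    baseline = [
        (k, float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for k, v in sorted(base.items())
    ]
    return ODCorrelationProfile(
        per_k=per_k,
        baseline_per_k=baseline,
        n_randomizations=n_randomizations,
        rng_seed=seed,
    )
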