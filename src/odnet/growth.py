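"""Neutral, biochemistry-constrained growth of metabolic reaction sets.

A model metabolism grows on a fixed background universe of possible
reactions (restricted to its giant connected component).  Starting from a
single seed reaction, each time step either adds, with probability ``p``, a
uniformly chosen reaction that is not yet in the set but neighbours it in
the background, or, with probability ``1 - p``, removes a uniformly chosen
leaf (a member with exactly one link in the induced subgraph).  No fitness
criterion enters: growth is constrained only by adjacency, i.e. biochemical
compatibility with the existing metabolism.

An ensemble of runs size-matched to a collection of organisms, pooled into a
union network, can then be analysed exactly like a real multi-organism
union (coarse-graining, OD profiles, correlation functions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError, StalledGrowthError
from .network import ReactionNetwork


@dataclass
class BackgroundNetwork:
    """A reaction universe on which model metabolisms grow.

    Adjacency is undirected: a reaction can attach to a metabolism through
    either a shared substrate or a shared product.  With
    ``giant_component_only`` (the default) the background is restricted to
    its largest weakly connected component before any run.
    """

    projection: ReactionNetwork
    giant_component_only: bool = True
    _adjacency: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.giant_component_only:
            self.projection = self.projection.giant_weak_component()
        self._adjacency = self.projection.undirected_adjacency()

    @property
    def nodes(self) -> set[str]:
        return self.projection.nodes

    def neighbors(self, r: str) -> set[str]:
        return self._adjacency[r]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth run.

    ``seed_mode`` is "fixed" (``seed_reaction`` reused, typically a reaction
    present in all organisms) or "random" (a fresh uniform background
    reaction per run).  ``p`` is the per-step addition probability; the
    complementary event removes a leaf.  ``max_steps=None`` runs until the
    target size is reached.
    """

    seed_mode: str = "fixed"
    seed_reaction: str | None = None
    p: float = 1.0
    target_size: int = 1
    max_steps: int | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.seed_mode not in ("fixed", "random"):
            raise ParameterError("seed_mode must be 'fixed' or 'random'")
        if not 0.0 < self.p <= 1.0:
            raise ParameterError("p must lie in (0, 1]")
        if self.target_size < 1:
            raise ParameterError("target_size must be >= 1")
        if self.seed_mode == "fixed" and self.seed_reaction is None:
            raise ParameterError("fixed seed_mode requires seed_reaction")


@dataclass
class GrowthModelRun:
    """Outcome of one growth run: the grown reaction set and bookkeeping."""

    params: GrowthParams
    seed_reaction: str
    final_set: frozenset[str]
    steps_taken: int
    reached_target: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed_mode": self.params.seed_mode,
                "seed_reaction": self.seed_reaction,
                "p": self.params.p,
                "target_size": self.params.target_size,
                "rng_seed": self.params.rng_seed,
                "steps_taken": self.steps_taken,
                "reached_target": self.reached_target,
                "final_set": sorted(self.final_set),
            },
            sort_keys=True,
        )


def _uniform_pick(pool: set[str], rng: np.random.Generator) -> str:
    ordered = sorted(pool)
    return ordered[int(rng.integers(len(ordered)))]


def grow(
    background: BackgroundNetwork,
    params: GrowthParams,
    rng: np.random.Generator | None = None,
) -> GrowthModelRun:
    """Run the neutral growth model once.

    The seed reaction is protected from removal so the set can always regrow.
    With ``p = 1`` the run performs exactly ``target_size - 1`` additions.
    An empty frontier before the target size is a
    :class:`~odnet.errors.StalledGrowthError` (silent truncation would break
    size-matching to organisms), while hitting ``max_steps`` returns the
    partial run with ``reached_target=False``.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    if params.seed_mode == "random":
        seed = _uniform_pick(background.nodes, rng)
    else:
        seed = params.seed_reaction
        if seed not in background.nodes:
            raise ParameterError(f"seed reaction {seed!r} not in background")
    if params.target_size > len(background.nodes):
        raise ParameterError("target_size exceeds the background size")

    current = {seed}
    frontier = set(background.neighbors(seed))
    steps = 0
    while len(current) < params.target_size:
        if params.max_steps is not None and steps >= params.max_steps:
            break
        steps += 1
        if params.p >= 1.0 or rng.random() < params.p:
            if not frontier:
                raise StalledGrowthError(len(current), params.target_size, current)
            pick = _uniform_pick(frontier, rng)
            current.add(pick)
            frontier.discard(pick)
            frontier |= background.neighbors(pick) - current
        else:
            leaves = {
                v
                for v in current
                if v != seed and len(background.neighbors(v) & current) == 1
            }
            if leaves:
                current.discard(_uniform_pick(leaves, rng))
                frontier = {
                    u for v in current for u in background.neighbors(v)
                } - current
            # no removable leaf: the step is a no-op
    return GrowthModelRun(
        params=params,
        seed_reaction=seed,
        final_set=frozenset(current),
        steps_taken=steps,
        reached_target=len(current) >= params.target_size,
    )


def generate_ensemble(
    background: BackgroundNetwork,
    sizes: Sequence[int],
    seed_mode: str = "fixed",
    seed_reaction: str | None = None,
    p: float = 1.0,
    rng_seed: int = 0,
    max_steps: int | None = None,
) -> list[GrowthModelRun]:
    """One growth run per requested size, independently reproducible.

    Per-run RNG streams are spawned from the master seed, so any single run
    can be replayed in isolation.  A stalled run is kept in the ensemble as a
    partial result (``reached_target=False``) and the ensemble continues.
    """
    master = np.random.SeedSequence(rng_seed)
    children = master.spawn(len(sizes))
    runs: list[GrowthModelRun] = []
    for size, child in zip(sizes, children):
        params = GrowthParams(
            seed_mode=seed_mode,
            seed_reaction=seed_reaction,
            p=p,
            target_size=int(size),
            max_steps=max_steps,
            rng_seed=rng_seed,
        )
        rng = np.random.default_rng(child)
        try:
            runs.append(grow(background, params, rng=rng))
        except StalledGrowthError as exc:
            runs.append(
                GrowthModelRun(
                    params=params,
                    seed_reaction=seed_reaction or "",
                    final_set=exc.achieved_set,
                    steps_taken=exc.achieved_size - 1,
                    reached_target=False,
                )
            )
    return runs


def model_union(
    runs: Sequence[GrowthModelRun], background: BackgroundNetwork
) -> ReactionNetwork:
    """Pool an ensemble of runs into an OD-tagged union network.

    Each run plays the role of one organism: od(r) = number of runs whose
    final set contains r.  Edges are the background edges restricted to the
    union, so the result is directly consumable by the coarse-graining and
    profile statistics.
    """
    if not runs:
        raise ParameterError("ensemble is empty")
    membership: dict[str, set[str]] = {}
    for i, run in enumerate(runs):
        label = f"run{i:04d}"
        for r in run.final_set:
            membership.setdefault(r, set()).add(label)
    nodes = set(membership)
    edges = {
        (a, b)
        for a, b in background.projection.edges
        if a in nodes and b in nodes
    }
    return ReactionNetwork(
        nodes=nodes,
        edges=edges,
        membership={r: frozenset(v) for r, v in membership.items()},
    )


def write_ensemble_summary(
    runs: Sequence[GrowthModelRun], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("run_id\tseed_reaction\tsize\tsteps\treached_target\n")
        for i, run in enumerate(runs):
            fh.write(
                f"run{i:04d}\t{run.seed_reaction}\t{len(run.final_set)}\t"
                f"{run.steps_taken}\t{run.reached_target}\n"
            )
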