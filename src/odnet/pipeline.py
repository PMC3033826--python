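"""End-to-end analysis orchestration with reproducible reports.

``run_analysis`` drives the full chain — build (or simulate) the bipartite
network, prune currency metabolites, project to reactions, tag organism
degree, coarse-grain, score against the reshuffling null, profile OD against
distance from the centre, compute the same-OD correlation and optionally
grow and analyse a size-matched neutral-model ensemble — and records every
seed and parameter in the report's provenance block, so an identical config
and master seed reproduce a byte-identical JSON report.

One master seed fans out to named per-stage streams (universe, phylogeny,
z-score, correlation, growth, model statistics), so any stage can be re-run
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .coarsegrain import coarse_grain, core_sizes, size_histogram, supernode_zscore
from .errors import ComparisonError, ConfigError, DegenerateNullError
from .growth import BackgroundNetwork, generate_ensemble, model_union
from .network import (
    build_union,
    od_species_consistency,
    project_to_reactions,
    prune_currency_metabolites,
    read_reaction_table,
)
from .profiles import central_node, od_vs_distance, same_od_correlation
from .synthetic import PhylogenySpec, SyntheticDataset, UniverseParams, generate_universe, evolve_organisms

logger = logging.getLogger(__name__)

#: Fixed stage order for deriving per-stage seeds from the master seed.
_STAGES = ("universe", "phylogeny", "zscore", "correlation", "growth", "model_stats")


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    Exactly one input mode must be used: a reaction-table path
    (``reaction_table``) or the synthetic generator (``synthetic=True``).
    """

    reaction_table: str | None = None
    background_table: str | None = None
    synthetic: bool = False
    universe: UniverseParams = field(default_factory=UniverseParams)
    phylogeny: PhylogenySpec = field(default_factory=PhylogenySpec)
    prune_threshold: int = 10
    od_bin_width: int = 1
    core_bin_widths: tuple[int, ...] | None = None
    n_randomizations: int = 20
    max_k: int = 10
    run_growth: bool = False
    growth_p: float = 1.0
    growth_seed_mode: str = "fixed"
    growth_seed_reaction: str | None = None
    rng_seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.synthetic == (self.reaction_table is not None):
            raise ConfigError(
                "exactly one of reaction_table or synthetic must be set"
            )
        if self.prune_threshold < 1:
            raise ConfigError("prune_threshold must be >= 1")
        if self.od_bin_width < 1:
            raise ConfigError("od_bin_width must be >= 1")
        if self.n_randomizations < 2:
            raise ConfigError("n_randomizations must be >= 2")
        if self.max_k < 1:
            raise ConfigError("max_k must be >= 1")
        if self.run_growth and not self.synthetic and self.background_table is None:
            raise ConfigError("growth analysis needs a background table")

    def stage_seed(self, stage: str) -> int:
        """Per-stage 31-bit seed derived from the master seed."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % 2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["core_bin_widths"] = list(self.effective_core_bin_widths())
        d.pop("out_dir", None)  # output location does not affect any statistic
        return d

    def effective_core_bin_widths(self) -> tuple[int, ...]:
        return self.core_bin_widths or (self.od_bin_width,)


@dataclass
class AnalysisReport:
    """Machine-readable result of ``run_analysis``; serialises to JSON."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=1, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "AnalysisReport":
        return cls(json.loads(Path(path).read_text()))


def _profile_stats(net, cfg: AnalysisConfig) -> dict:
    """Centre, OD/distance profile, correlation and OD histogram of a union."""
    od = net.require_od()
    center = central_node(net)
    profile = od_vs_distance(net, center)
    corr = same_od_correlation(
        net,
        max_k=cfg.max_k,
        n_randomizations=cfg.n_randomizations,
        rng=cfg.stage_seed("correlation"),
    )
    out = {
        "center": center,
        "od_distance_profile": [list(t) for t in profile.per_distance],
        "global_mean_od": profile.global_mean_od,
        "unreachable_count": profile.unreachable_count,
        "correlation": {
            "per_k": [list(t) for t in corr.per_k],
            "baseline_per_k": [list(t) for t in corr.baseline_per_k],
            "n_randomizations": corr.n_randomizations,
        },
        "od_histogram": {str(k): v for k, v in sorted(Counter(od.values()).items())},
    }
    return out


def _coarse_stats(net, cfg: AnalysisConfig) -> dict:
    sg = coarse_grain(net, cfg.od_bin_width)
    out: dict = {
        "n_supernodes": len(sg.supernodes),
        "mean_size": sg.mean_size(),
        "size_histogram": {str(k): v for k, v in sorted(size_histogram(sg).items())},
        "core_sizes": {},
    }
    for w in cfg.effective_core_bin_widths():
        report = core_sizes(coarse_grain(net, w))
        out["core_sizes"][str(w)] = dataclasses.asdict(report)
    try:
        zs = supernode_zscore(
            net,
            od_bin_width=cfg.od_bin_width,
            n_randomizations=cfg.n_randomizations,
            rng=cfg.stage_seed("zscore"),
        )
        out["zscore"] = dataclasses.asdict(zs)
    except DegenerateNullError as exc:
        out["zscore"] = {"error": str(exc)}
    return out


def _pick_fixed_seed(union) -> str:
    """Recipe for the fixed growth seed: a maximum-OD reaction (present in
    the most organisms), lexicographically smallest on ties."""
    od = union.require_od()
    od_max = max(od.values())
    return min(r for r in union.nodes if od[r] == od_max)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full pipeline and return (and optionally write) the report."""
    config.validate()
    report: dict = {
        "provenance": {
            "odnet_version": __version__,
            "config": config.to_dict(),
            "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        }
    }

    # --- build -----------------------------------------------------------
    if config.synthetic:
        universe_params = dataclasses.replace(
            config.universe, rng_seed=config.stage_seed("universe")
        )
        phylo_spec = dataclasses.replace(
            config.phylogeny, rng_seed=config.stage_seed("phylogeny")
        )
        universe = generate_universe(universe_params)
        dataset = evolve_organisms(universe, phylo_spec)
        bip = _dataset_union_bipartite(dataset)
        background_bip = universe
        organism_sizes = [len(s) for _, s in sorted(dataset.organism_sets.items())]
    else:
        bip = read_reaction_table(config.reaction_table)
        background_bip = (
            read_reaction_table(config.background_table, allow_empty_organisms=True)
            if config.background_table
            else None
        )
        organism_sizes = None

    n_met_before, n_rxn = len(bip.metabolites), len(bip.reactions)
    pruned = prune_currency_metabolites(bip, config.prune_threshold)
    union = project_to_reactions(pruned, require_od=True)
    if organism_sizes is None:
        orgs = sorted({o for s in union.membership.values() for o in s})
        organism_sizes = [
            sum(1 for s in union.membership.values() if o in s) for o in orgs
        ]
    report["network"] = {
        "n_metabolites_before_pruning": n_met_before,
        "n_metabolites_after_pruning": len(pruned.metabolites),
        "n_reactions": n_rxn,
        "n_nodes": union.n_nodes,
        "n_edges": union.n_edges,
        "n_organisms": len({o for s in union.membership.values() for o in s}),
    }

    frac, discordant = od_species_consistency(union)
    report["consistency"] = {
        "fraction_identical": frac,
        "n_discordant_pairs": len(discordant),
    }

    # --- coarse-grain / z-score / cores ---------------------------------
    report["coarse_grain"] = _coarse_stats(union, config)

    # --- centre, profiles, correlation ----------------------------------
    report["structure"] = _profile_stats(union, config)

    # --- neutral growth model -------------------------------------------
    if config.run_growth:
        bg_proj = project_to_reactions(
            prune_currency_metabolites(background_bip, config.prune_threshold)
        )
        background = BackgroundNetwork(bg_proj)
        seed_reaction = config.growth_seed_reaction
        if config.growth_seed_mode == "fixed" and seed_reaction is None:
            seed_reaction = _pick_fixed_seed(union)
            if seed_reaction not in background.nodes:
                seed_reaction = min(background.nodes)
        sizes = [min(s, len(background.nodes)) for s in organism_sizes]
        runs = generate_ensemble(
            background,
            sizes,
            seed_mode=config.growth_seed_mode,
            seed_reaction=seed_reaction,
            p=config.growth_p,
            rng_seed=config.stage_seed("growth"),
        )
        munion = model_union(runs, background)
        model_cfg = dataclasses.replace(config)  # same widths/replicates
        report["growth_model"] = {
            "n_runs": len(runs),
            "seed_mode": config.growth_seed_mode,
            "seed_reaction": seed_reaction if config.growth_seed_mode == "fixed" else None,
            "n_stalled": sum(0 if r.reached_target else 1 for r in runs),
            "union": {
                "n_nodes": munion.n_nodes,
                "n_edges": munion.n_edges,
                "max_od": max(munion.require_od().values()),
            },
            "coarse_grain": _coarse_stats(munion, model_cfg),
            "structure": _profile_stats(munion, model_cfg),
        }

    result = AnalysisReport(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.write(out / "report.json")
        union.write_graphml(out / "union.graphml")
        union.write_edgelist(out / "union_edges.tsv")
    return result


def _dataset_union_bipartite(dataset: SyntheticDataset):
    """Bipartite network of the reactions present in >= 1 organism."""
    from .network import BipartiteMetabolicNetwork

    membership = dataset.union_membership()
    return BipartiteMetabolicNetwork(
        metabolites=set(dataset.universe.metabolites),
        reactions=set(membership),
        substrate_links={
            (m, r) for m, r in dataset.universe.substrate_links if r in membership
        },
        product_links={
            (r, m) for r, m in dataset.universe.product_links if r in membership
        },
        membership=membership,
    )


def compare_real_vs_model(
    report_a: AnalysisReport, report_b: AnalysisReport
) -> dict:
    """Per-distance difference of shell-mean OD plus OD-histogram divergence.

    Both reports must contain distance profiles with overlapping distance
    ranges; profiles of different lengths are truncated to the shared range
    (logged).  Histogram divergence is the total-variation distance between
    the normalised OD histograms.  No significance claims are made.
    """

    def profile(rep: AnalysisReport) -> dict[int, float]:
        sect = rep.data.get("structure", {})
        return {int(d): m for d, m, _ in sect.get("od_distance_profile", [])}

    pa, pb = profile(report_a), profile(report_b)
    shared = sorted(set(pa) & set(pb))
    if not shared:
        raise ComparisonError("distance profiles have disjoint ranges")
    if len(shared) < max(len(pa), len(pb)):
        logger.info("profiles truncated to shared distance range 0..%d", shared[-1])
    rows = [
        {"distance": d, "mean_od_a": pa[d], "mean_od_b": pb[d], "diff": pa[d] - pb[d]}
        for d in shared
    ]

    def hist(rep: AnalysisReport) -> dict[int, float]:
        h = rep.data.get("structure", {}).get("od_histogram", {})
        total = sum(h.values()) or 1
        return {int(k): v / total for k, v in h.items()}

    ha, hb = hist(report_a), hist(report_b)
    keys = set(ha) | set(hb)
    tv = 0.5 * sum(abs(ha.get(k, 0.0) - hb.get(k, 0.0)) for k in keys)
    return {"per_distance": rows, "od_histogram_total_variation": tv}


# ---------------------------------------------------------------------------
# plain-text key=value config files

_UNIVERSE_KEYS = {"n_reactions", "n_metabolites", "mean_out_degree", "chain_bias"}
_PHYLO_KEYS = {
    "n_organisms",
    "tree_newick",
    "root_genome_size",
    "gain_rate",
    "loss_rate",
    "branch_lengths",
}
_BOOL_KEYS = {"synthetic", "run_growth"}


def parse_config(path: str | Path) -> AnalysisConfig:
    """Parse the plain-text ``key = value`` config dialect.

    Lines are ``key = value``; ``#`` starts a comment; keys are the flat
    field names of :class:`AnalysisConfig` plus the universe/phylogeny
    parameter names, e.g.::

        synthetic = true
        n_organisms = 16
        prune_threshold = 10
        od_bin_width = 1
        rng_seed = 42
    """
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        kv[key] = value
    return config_from_mapping(kv)


def config_from_mapping(kv: dict[str, str]) -> AnalysisConfig:
    cfg = AnalysisConfig()
    uni: dict = {}
    phy: dict = {}
    for key, value in kv.items():
        if key in _UNIVERSE_KEYS:
            uni[key] = _coerce(value)
        elif key in _PHYLO_KEYS:
            phy[key] = _coerce(value)
        elif key == "core_bin_widths":
            cfg.core_bin_widths = tuple(int(v) for v in value.split(",") if v)
        elif hasattr(cfg, key):
            if key in _BOOL_KEYS:
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            else:
                setattr(cfg, key, _coerce(value))
        else:
            raise ConfigError(f"unknown config key {key!r}")
    if uni:
        cfg.universe = dataclasses.replace(cfg.universe, **uni)
    if phy:
        cfg.phylogeny = dataclasses.replace(cfg.phylogeny, **phy)
    return cfg


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value.lower() in ("none", ""):
        return None
    return value
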