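"""Functional-set networks bridged by divergently paired genes.

Two maps over a collection of functional gene sets are supported: an
*overlap map* (edges weighted by the Simpson overlap rate
``|A∩B| / min(|A|,|B|)``) and an *interaction map* (edges weighted by the
rate of DPG pairs bridging the two sets — one member exclusive to each
set — normalized by the smaller set size).  Modules are detected by
greedy cohesiveness maximisation in the style of ClusterONE: grow groups
from high-degree seeds, merge highly overlapping groups (Simpson
coefficient), and attach a one-sided Mann-Whitney quality p-value
comparing internal against boundary edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .geometry import DpgPair

__all__ = [
    "FunctionalSetCollection",
    "SetNetwork",
    "Module",
    "filter_categories",
    "overlap_rate",
    "interaction_rate",
    "build_network",
    "coverage_percent",
    "dpg_fraction_percent",
    "cohesiveness",
    "cluster_modules",
    "simpson",
]


@dataclass
class FunctionalSetCollection:
    """Named gene sets with an optional source label per set."""

    sets: dict[str, set[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def overlap_rate(a: set[str], b: set[str]) -> float:
    """Simpson overlap: ``|A∩B| / min(|A|,|B|)``."""
    if not a or not b:
        raise ValueError("overlap_rate requires non-empty sets")
    return len(a & b) / min(len(a), len(b))


simpson = overlap_rate


def interaction_rate(
    a: set[str], b: set[str], pairs: Sequence[DpgPair]
) -> tuple[int, float, list[DpgPair]]:
    """Bridging-pair count and rate between two sets.

    A pair bridges (A, B) when one member lies in A but not B and the
    other in B but not A; a pair inside the intersection does not count.
    The rate normalizes by ``min(|A|,|B|)``, paralleling the Simpson
    convention used for overlaps.
    """
    if not a or not b:
        raise ValueError("interaction_rate requires non-empty sets")
    only_a, only_b = a - b, b - a
    bridging = [
        p
        for p in pairs
        if (p.minus_gene in only_a and p.plus_gene in only_b)
        or (p.minus_gene in only_b and p.plus_gene in only_a)
    ]
    return len(bridging), len(bridging) / min(len(a), len(b)), bridging


def filter_categories(
    collection: FunctionalSetCollection,
    min_size: int = 6,
    max_overlap: float = 0.8,
) -> FunctionalSetCollection:
    """Reduce a collection to representative categories.

    Retains sets with size strictly greater than ``min_size - 1`` (i.e.
    size > 5 at defaults) whose Simpson overlap with every already-retained
    set is strictly below ``max_overlap``.  Sets are considered greedily in
    descending size order, ties broken by name, which makes the filter
    deterministic.
    """
    order = sorted(collection.sets, key=lambda n: (-len(collection.sets[n]), n))
    kept: list[str] = []
    for name in order:
        s = collection.sets[name]
        if len(s) < min_size:
            continue
        if all(overlap_rate(s, collection.sets[k]) < max_overlap for k in kept):
            kept.append(name)
    return FunctionalSetCollection(
        sets={n: set(collection.sets[n]) for n in kept},
        sources={n: collection.sources[n] for n in kept if n in collection.sources},
    )


@dataclass
class SetNetwork:
    """Graph over functional sets; edges carry rates and bridging pairs."""

    graph: nx.Graph
    map_kind: str  # "interaction" or "overlap"
    cutoff: float
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def coverage_percent(n_covered: int, n_total: int) -> float:
    """Coverage as a percentage: ``100 * n_covered / n_total``."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_covered / n_total


def dpg_fraction_percent(n_dpg: int, n_category: int) -> float:
    """Percentage of a category's genes that are DPG genes."""
    return coverage_percent(n_dpg, n_category)


def build_network(
    collection: FunctionalSetCollection,
    pairs: Sequence[DpgPair],
    map_kind: str = "interaction",
    cutoff: float | None = None,
    annotated_dpg_genes: Iterable[str] | None = None,
) -> SetNetwork:
    """Build the overlap or interaction map over a filtered collection.

    An edge joins every set pair whose rate strictly exceeds ``cutoff``
    (defaults: 0.07 for the interaction map, 0.30 for the overlap map).
    Coverage statistics — number of sets touched by retained edges, number
    of distinct bridging DPG genes, and relative coverage against the
    annotated DPG-gene universe — are attached to the result.
    """
    if map_kind not in ("interaction", "overlap"):
        raise ValueError(f"unknown map kind {map_kind!r}")
    if cutoff is None:
        cutoff = 0.07 if map_kind == "interaction" else 0.30

    g = nx.Graph(map_kind=map_kind, cutoff=cutoff)
    for name, members in collection.sets.items():
        g.add_node(name, size=len(members))

    for a, b in combinations(collection.sets, 2):
        sa, sb = collection.sets[a], collection.sets[b]
        if map_kind == "interaction":
            n_bridge, rate, bridging = interaction_rate(sa, sb, pairs)
            if rate > cutoff:
                g.add_edge(a, b, weight=rate, rate=rate, n_bridging=n_bridge,
                           bridging_pairs=bridging)
        else:
            n_overlap = len(sa & sb)
            rate = overlap_rate(sa, sb)
            if rate > cutoff:
                g.add_edge(a, b, weight=rate, rate=rate, n_overlap_genes=n_overlap)

    covered_sets = {n for e in g.edges for n in e}
    coverage: dict[str, float] = {"n_sets_covered": float(len(covered_sets))}
    if map_kind == "interaction":
        covered_genes: set[str] = set()
        for _, _, data in g.edges(data=True):
            for p in data["bridging_pairs"]:
                covered_genes.update(p.genes)
        coverage["n_dpg_genes_covered"] = float(len(covered_genes))
        if annotated_dpg_genes is not None:
            universe = set(annotated_dpg_genes)
            if universe:
                coverage["relative_coverage_pct"] = coverage_percent(
                    len(covered_genes & universe), len(universe)
                )
    return SetNetwork(graph=g, map_kind=map_kind, cutoff=cutoff, coverage=coverage)


def cohesiveness(members: Iterable[str], graph: nx.Graph, penalty: float = 2.0) -> float:
    """Cohesiveness of a node group: ``w_in / (w_in + w_bound + penalty*|V|)``.

    ``w_in`` sums weights of edges with both endpoints inside the group,
    ``w_bound`` those with exactly one endpoint inside.
    """
    v = set(members)
    if not v:
        raise ValueError("cohesiveness of an empty group is undefined")
    w_in = 0.0
    w_bound = 0.0
    for node in v:
        if node not in graph:
            raise ValueError(f"node {node!r} not in network")
        for _, other, data in graph.edges(node, data=True):
            w = data.get("weight", 1.0)
            if other in v:
                w_in += w / 2.0  # internal edges visited from both ends
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(v)
    return w_in / denom if denom > 0 else 0.0


@dataclass
class Module:
    """A detected module: member sets, cohesiveness, and quality p-value."""

    members: frozenset[str]
    cohesiveness: float
    p_value: float

    def __len__(self) -> int:
        return len(self.members)


def _grow(seed: str, graph: nx.Graph, penalty: float) -> set[str]:
    """Greedy local search: add/remove one node while cohesiveness strictly rises."""
    group = {seed}
    score = cohesiveness(group, graph, penalty)
    while True:
        best_move: tuple[str, str] | None = None
        best_score = score
        frontier = {n for m in group for n in graph.neighbors(m)} - group
        for n in sorted(frontier):
            s = cohesiveness(group | {n}, graph, penalty)
            if s > best_score:
                best_score, best_move = s, ("add", n)
        if len(group) > 1:
            for n in sorted(group):
                s = cohesiveness(group - {n}, graph, penalty)
                if s > best_score:
                    best_score, best_move = s, ("remove", n)
        if best_move is None:
            return group
        op, node = best_move
        group = group | {node} if op == "add" else group - {node}
        score = best_score


def _module_pvalue(members: set[str], graph: nx.Graph) -> float:
    """One-sided Mann-Whitney U: internal edge weights vs boundary edge weights."""
    internal, boundary = [], []
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        ina, inb = a in members, b in members
        if ina and inb:
            internal.append(w)
        elif ina or inb:
            boundary.append(w)
    if not internal:
        return 1.0
    if not boundary:
        # an isolated group: no boundary evidence against it
        return 0.0 if internal else 1.0
    res = mannwhitneyu(internal, boundary, alternative="greater")
    return float(res.pvalue)


def cluster_modules(
    network: SetNetwork | nx.Graph,
    penalty: float = 2.0,
    merge_threshold: float = 0.8,
    min_size: int = 3,
) -> list[Module]:
    """Detect modules by multi-pass greedy cohesiveness growth.

    Seeds are taken in order of decreasing weighted degree among nodes not
    yet covered by any grown group (ties by name); each seed is grown by
    single add/remove moves while cohesiveness strictly increases.  Growth
    continues until every node is covered or yields no group.  Groups whose
    Simpson coefficient reaches ``merge_threshold`` are merged transitively;
    groups below ``min_size`` are dropped.  Deterministic: no randomness.
    """
    graph = network.graph if isinstance(network, SetNetwork) else network
    if graph.number_of_edges() == 0:
        return []

    wdeg = {
        n: sum(d.get("weight", 1.0) for _, _, d in graph.edges(n, data=True))
        for n in graph.nodes
    }
    covered: set[str] = set()
    groups: list[set[str]] = []
    while True:
        seeds = sorted(
            (n for n in graph.nodes if n not in covered and wdeg[n] > 0),
            key=lambda n: (-wdeg[n], n),
        )
        if not seeds:
            break
        grown = _grow(seeds[0], graph, penalty)
        covered.add(seeds[0])
        covered |= grown
        if grown not in groups:
            groups.append(grown)

    # transitive Simpson merge
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(groups)), 2):
            if simpson(groups[i], groups[j]) >= merge_threshold:
                groups[i] = groups[i] | groups[j]
                del groups[j]
                merged = True
                break

    modules = [
        Module(
            members=frozenset(g),
            cohesiveness=cohesiveness(g, graph, penalty),
            p_value=_module_pvalue(g, graph),
        )
        for g in groups
        if len(g) >= min_size
    ]
    modules.sort(key=lambda m: (-len(m.members), sorted(m.members)))
    return modules


def module_report(modules: Sequence[Module]) -> pd.DataFrame:
    """Tabulate modules: members, size, cohesiveness, p-value."""
    return pd.DataFrame(
        [
            {
                "module": i + 1,
                "n_members": len(m),
                "cohesiveness": m.cohesiveness,
                "p_value": m.p_value,
                "members": ",".join(sorted(m.members)),
            }
            for i, m in enumerate(modules)
        ]
    )
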