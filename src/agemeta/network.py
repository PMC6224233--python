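"""Zero-order PPI network, hub selection, and permutation-tested modules.

The zero-order network is the induced subgraph of a scored interaction
database on the consensus ("seed") genes: only seed-seed edges with a
combined score above the confidence threshold (>900 on the 0-1000
convention) are retained. Hubs are selected by degree (DC >= 10) combined
with a betweenness-centrality ranking cut at the top 10% of the consensus
list. Connected components split into one "continent" (the largest) and
smaller "islands"; the continent is partitioned into candidate modules by
greedy-modularity community detection, and every candidate of size >= 5 is
assigned a degree-binned permutation p-value for its internal edge density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ModuleResult:
    """A candidate module: member genes, internal edges, permutation p."""

    module_id: str
    members: list[str]
    n_internal_edges: int
    p_value: float
    kind: str = "module"  # "module" (continent partition) or "island"
    annotations: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def build_zero_order(
    edges: pd.DataFrame,
    seed_genes: Iterable[str],
    score_threshold: float = 900.0,
) -> tuple[nx.Graph, dict]:
    """Induced subgraph on the seed genes, keeping high-confidence edges.

    ``edges`` needs columns ``protein1, protein2, combined_score`` (STRING
    0-1000 convention). Self-loops and duplicate pairs are collapsed; seeds
    with no retained edge are excluded from the graph but counted in the
    returned log dict.
    """
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("seed gene list is empty")
    g = nx.Graph()
    for a, b, score in edges[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if a == b or a not in seeds or b not in seeds:
            continue
        if float(score) < score_threshold:
            continue
        if g.has_edge(a, b):
            # keep the highest score among duplicate reports of a pair
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], float(score))
        else:
            g.add_edge(a, b, combined_score=float(score))
    connected = set(g.nodes)
    log = {
        "n_seeds": len(seeds),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_isolated_seeds": len(seeds - connected),
    }
    if g.number_of_nodes() == 0:
        logger.warning("build_zero_order: no seed-seed edge passed the threshold")
    else:
        logger.info("build_zero_order: %(n_nodes)d nodes, %(n_edges)d edges, "
                    "%(n_isolated_seeds)d isolated seeds", log)
    return g, log


def centralities(graph: nx.Graph, directions: pd.Series | None = None) -> pd.DataFrame:
    """Degree and unnormalized betweenness centrality per node.

    Betweenness is Brandes' shortest-path betweenness on the undirected
    unweighted graph with each unordered pair counted once; disconnected
    graphs are handled naturally (pairs in different components contribute
    nothing). Sorted by betweenness descending with degree then gene ID as
    tie-breaks, so the ranking is total and row-order invariant.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    bc = nx.betweenness_centrality(graph, normalized=False)
    table = pd.DataFrame({
        "gene": sorted(graph.nodes),
    })
    table["degree"] = [graph.degree[g] for g in table["gene"]]
    table["betweenness"] = [bc[g] for g in table["gene"]]
    if directions is not None:
        table["direction"] = table["gene"].map(directions)
    table = table.sort_values(
        ["betweenness", "degree", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def select_hubs(
    hub_table: pd.DataFrame,
    dc_min: int = 10,
    top_fraction: float = 0.10,
    n_total_genes: int | None = None,
) -> pd.DataFrame:
    """Hub genes: degree >= ``dc_min`` AND betweenness rank in the top slice.

    The top-10% denominator is the number of consensus genes (the seed list
    that generated the network), not only the connected nodes; pass it via
    ``n_total_genes``. Defaults to the table size when not given.
    """
    total = int(n_total_genes) if n_total_genes is not None else len(hub_table)
    rank_cut = math.ceil(top_fraction * total)
    out = hub_table.copy()
    out["hub"] = (out["degree"] >= dc_min) & (out["rank"] <= rank_cut)
    logger.info("select_hubs: %d hubs (degree >= %d, rank <= %d of %d)",
                int(out["hub"].sum()), dc_min, rank_cut, total)
    return out


def _internal_edges(graph: nx.Graph, nodes: Sequence[str]) -> int:
    node_set = set(nodes)
    return sum(1 for a, b in graph.edges(node_set) if a in node_set and b in node_set)


def _degree_bins(graph: nx.Graph, nodes: Sequence[str]) -> dict[str, np.ndarray]:
    """Group nodes into logarithmic degree bins for degree-matched sampling."""
    bins: dict[int, list[str]] = {}
    for n in nodes:
        b = int(np.floor(np.log2(max(graph.degree[n], 1))))
        bins.setdefault(b, []).append(n)
    return {n: np.array(sorted(bins[int(np.floor(np.log2(max(graph.degree[n], 1))))]))
            for n in nodes}


def module_permutation_p(
    graph: nx.Graph,
    members: Sequence[str],
    pool_nodes: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[int, float]:
    """Degree-binned permutation p-value for a candidate module.

    Draws ``n_perm`` random node sets of the same size from ``pool_nodes``
    (each member replaced by a random node from its degree bin) and compares
    internal edge counts; p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    observed = _internal_edges(graph, members)
    pool = sorted(pool_nodes)
    node_to_bin = _degree_bins(graph, pool)
    member_bins = []
    for m in members:
        if m in node_to_bin:
            member_bins.append(node_to_bin[m])
        else:  # member outside the pool (island nodes): match by nearest degree bin
            target = int(np.floor(np.log2(max(graph.degree[m], 1))))
            pool_bins = {int(np.floor(np.log2(max(graph.degree[n], 1)))) for n in pool}
            best = min(pool_bins, key=lambda b: abs(b - target))
            member_bins.append(np.array(sorted(
                n for n in pool if int(np.floor(np.log2(max(graph.degree[n], 1)))) == best
            )))
    count = 0
    size = len(members)
    for _ in range(n_perm):
        picked: set[str] = set()
        for candidates in member_bins:
            choice = candidates[rng.integers(len(candidates))]
            tries = 0
            while choice in picked and tries < 20:
                choice = candidates[rng.integers(len(candidates))]
                tries += 1
            if choice in picked:  # bin exhausted; fall back to whole pool
                remaining = [n for n in pool if n not in picked]
                choice = remaining[rng.integers(len(remaining))]
            picked.add(choice)
        if len(picked) == size and _internal_edges(graph, list(picked)) >= observed:
            count += 1
    return observed, (1 + count) / (n_perm + 1)


def components_and_modules(
    graph: nx.Graph,
    min_size: int = 5,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[list[list[str]], list[ModuleResult]]:
    """Connected components plus significant modules of the continent.

    Components are sorted by size descending (the first is the continent).
    The continent is partitioned with deterministic greedy-modularity
    (Clauset-Newman-Moore) community detection; islands of size >=
    ``min_size`` are candidate modules too. Every candidate receives a
    degree-binned permutation p-value (null sets drawn from the continent);
    only candidates with ``p < alpha`` and size >= ``min_size`` are
    returned, but all components are.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if n_perm < 100:
        logger.warning("components_and_modules: n_perm=%d gives p resolution %.3g",
                       n_perm, 1.0 / (n_perm + 1))
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: (-len(c), c[0]))
    continent = comps[0]
    sub = graph.subgraph(continent)
    candidates: list[tuple[str, list[str], str]] = []
    if len(continent) >= min_size:
        communities = nx.community.greedy_modularity_communities(sub)
        communities = sorted((sorted(c) for c in communities),
                             key=lambda c: (-len(c), c[0]))
        for i, comm in enumerate(communities, start=1):
            if len(comm) >= min_size:
                candidates.append((f"module_{i}", comm, "module"))
    for j, comp in enumerate(comps[1:], start=1):
        if len(comp) >= min_size:
            candidates.append((f"island_{j}", comp, "island"))
    rng = np.random.default_rng(seed)
    modules: list[ModuleResult] = []
    for name, members, kind in candidates:
        obs, p = module_permutation_p(
            graph, members, continent, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        if p < alpha:
            modules.append(ModuleResult(
                module_id=name, members=members,
                n_internal_edges=obs, p_value=p, kind=kind,
            ))
    logger.info("components_and_modules: %d components, %d significant candidates "
                "(size >= %d, p < %g)", len(comps), len(modules), min_size, alpha)
    return comps, modules


def hub_table_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
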