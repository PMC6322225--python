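"""Topological summaries, Infomap communities, and the community quotient graph.

Conventions for disconnected graphs (a PXPN typically splits into many
connected components, some of them isolated "single nodes"):

* clustering coefficient: mean of local clustering over *all* nodes, with
  degree-<2 nodes contributing 0 (``count_zero=False`` excludes them
  instead);
* average shortest path: mean over reachable pairs within components;
  unreachable pairs are excluded rather than poisoning the mean.

*Specific density* normalizes the edge count not by all node pairs but by
the biologically possible crosstalks — node pairs whose pathway gene sets
actually intersect.
"""

from __future__ import annotations

import itertools
import random as _random
from dataclasses import dataclass, asdict

import igraph as ig
import networkx as nx

from .pathways import PathwayCollection

__all__ = [
    "density",
    "average_degree",
    "specific_density",
    "topology_summary",
    "detect_communities",
    "community_quotient",
    "TopologySummary",
    "CommunityPartition",
]


def density(n: int, e: int) -> float:
    """Graph density 2e / (n(n-1)) for an undirected simple graph."""
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2 * e / (n * (n - 1))


def average_degree(n: int, e: int) -> float:
    """Mean degree 2e/n."""
    if n < 1:
        raise ValueError("average degree undefined for an empty graph")
    return 2 * e / n


def specific_density(
    graph: nx.Graph, collection: PathwayCollection, min_region_size: int = 1
) -> tuple[int, int, float | None]:
    """(numerator, denominator, ratio): edges over possible crosstalks.

    The denominator counts node pairs *in the graph* whose pathway gene sets
    share at least ``min_region_size`` genes; the ratio is None when no
    crosstalk is possible.
    """
    for node in graph.nodes:
        if node not in collection:
            raise KeyError(f"graph node {node!r} not in pathway collection")
    denom = sum(
        1
        for a, b in itertools.combinations(sorted(graph.nodes), 2)
        if len(collection[a].genes & collection[b].genes) >= min_region_size
    )
    num = graph.number_of_edges()
    return num, denom, (num / denom if denom else None)


@dataclass
class TopologySummary:
    """The structural profile of one network."""

    nodes: int
    edges: int
    density: float | None
    specific_density: float | None
    specific_density_numerator: int | None
    specific_density_denominator: int | None
    average_degree: float | None
    clustering_coefficient: float | None
    average_shortest_path: float | None
    connected_components: int
    single_nodes: int

    def to_dict(self) -> dict:
        return asdict(self)


def _average_shortest_path(graph: nx.Graph) -> float | None:
    """Mean shortest-path length over reachable pairs within components."""
    total = 0
    pairs = 0
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())  # includes the 0 self-distance
            pairs += len(lengths) - 1
    return total / pairs if pairs else None


def topology_summary(
    graph: nx.Graph,
    collection: PathwayCollection | None = None,
    min_region_size: int = 1,
    count_zero: bool = True,
) -> TopologySummary:
    """Compute the full structural profile of a network.

    Specific density needs the pathway collection; without it those fields
    are None.
    """
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    num = den = ratio = None
    if collection is not None and n:
        num, den, ratio = specific_density(graph, collection, min_region_size)
    return TopologySummary(
        nodes=n,
        edges=e,
        density=density(n, e) if n >= 2 else None,
        specific_density=ratio,
        specific_density_numerator=num,
        specific_density_denominator=den,
        average_degree=average_degree(n, e) if n else None,
        clustering_coefficient=nx.average_clustering(graph, count_zeros=count_zero)
        if n
        else None,
        average_shortest_path=_average_shortest_path(graph),
        connected_components=nx.number_connected_components(graph),
        single_nodes=sum(1 for _, d in graph.degree() if d == 0),
    )


@dataclass
class CommunityPartition:
    """A hard partition of the nodes into communities, ids contiguous from 0."""

    assignment: dict
    seed: int
    method: str = "infomap"

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return out


def detect_communities(graph: nx.Graph, seed: int = 0, trials: int = 10) -> CommunityPartition:
    """Detect communities with the map-equation (Infomap) algorithm.

    The best of ``trials`` runs (by codelength) is kept; the result is
    deterministic given (graph, seed, trials).  Isolated nodes become
    singleton communities.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty graph")
    nodes = list(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    h = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges()]
    )
    state = _random.getstate()
    _random.seed(seed)
    try:
        clustering = h.community_infomap(trials=trials)
    finally:
        _random.setstate(state)
    membership = clustering.membership
    relabel: dict[int, int] = {}
    assignment = {}
    for node in nodes:
        raw = membership[index[node]]
        if raw not in relabel:
            relabel[raw] = len(relabel)
        assignment[node] = relabel[raw]
    return CommunityPartition(assignment=assignment, seed=seed)


def community_quotient(graph: nx.Graph, partition: CommunityPartition) -> nx.Graph:
    """Collapse communities to meta-nodes: the "network of networks".

    Meta-edge ``weight`` counts the original edges crossing the community
    pair; intra-community edges are excluded.
    """
    missing = [n for n in graph.nodes if n not in partition.assignment]
    if missing:
        raise KeyError(f"nodes missing from partition: {missing[:5]}")
    q = nx.Graph()
    for cid, members in partition.members().items():
        q.add_node(cid, members=sorted(map(str, members)), size=len(members))
    for u, v in graph.edges():
        cu, cv = partition.assignment[u], partition.assignment[v]
        if cu == cv:
            continue
        if q.has_edge(cu, cv):
            q[cu][cv]["weight"] += 1
        else:
            q.add_edge(cu, cv, weight=1)
    return q
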