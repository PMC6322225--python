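"""Four-step PXPN construction, GML network I/O, and pairwise comparison.

The pathway crosstalk perturbation network (PXPN) for a transition between
two physiological states is built in four steps:

1. enrich every pathway on the expression contrast and keep those with
   q < alpha — the nodes;
2. compute crosstalk regions (gene-set intersections) among those enriched
   pathways only — the candidate edges;
3. enrich each crosstalk region with the same enrichment function (a second,
   separate BH family);
4. assemble the undirected graph: enriched pathways as nodes, enriched
   regions as edges.  Enriched pathways with no enriched region remain as
   isolated "single nodes".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .enrichment import ExpressionMatrix, enrich, set_statistic
from .pathways import PathwayCollection, crosstalk_regions, jaccard

__all__ = [
    "TransitionSpec",
    "PxpnConfig",
    "build_pxpn",
    "write_gml",
    "read_gml",
    "compare_networks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionSpec:
    """Metadata naming an ordered pair of physiological states.

    E.g. HTD (health to disease), DTT (disease to treatment), TTH (treatment
    to health).  Undirected scoring makes the graph itself invariant to the
    direction; this record documents which contrast seeded the network.
    """

    name: str
    state_from: str
    state_to: str


@dataclass
class PxpnConfig:
    """Knobs of the PXPN pipeline.

    alpha is the enrichment q-value threshold for both pathways and
    crosstalk regions.  Pathways need ``min_pathway_size`` scored member
    genes to be tested; regions need ``min_region_test_size`` (size-1
    regions are meaningful crosstalk, so the default is 1).
    ``min_region_size`` is the smallest intersection that counts as
    crosstalk at all.
    """

    alpha: float = 0.05
    mode: str = "parametric"  # or "permutation"
    n_perm: int = 1000
    min_region_size: int = 1
    min_pathway_size: int = 2
    min_region_test_size: int = 1
    u_cap: float = 50.0
    seed: int | None = None
    statistic: object = field(default=set_statistic, repr=False)


def build_pxpn(
    expr: ExpressionMatrix,
    collection: PathwayCollection,
    alpha: float = 0.05,
    config: PxpnConfig | None = None,
    transition: TransitionSpec | None = None,
) -> nx.Graph:
    """Build the PXPN for one expression contrast.

    Returns an undirected :class:`networkx.Graph`; nodes carry ``name``,
    ``T`` (pathway statistic) and ``q``, edges carry ``region_size``, ``T``,
    ``q`` and the ``jaccard`` of the parent pathway gene sets.  An empty
    node set yields an empty graph, not an error.
    """
    cfg = config or PxpnConfig()
    cfg.alpha = alpha
    scored = set(expr.genes)
    if not scored & set(collection.universe):
        raise ValueError("expression matrix and pathway collection share no genes")

    common = dict(
        directed=False, u_cap=cfg.u_cap, mode=cfg.mode, n_perm=cfg.n_perm,
        seed=cfg.seed, statistic=cfg.statistic,
    )
    # step 1: perturbed pathways
    ptable = enrich(
        expr, collection.gene_sets(), alpha, min_set_size=cfg.min_pathway_size, **common
    )
    enriched_ids = sorted(ptable.loc[ptable["enriched"], "set_id"])
    logger.info(
        "pathways: %d tested, %d enriched at q<%g",
        int(ptable["tested"].sum()), len(enriched_ids), alpha,
    )

    g = nx.Graph()
    if transition is not None:
        g.graph.update(
            transition=transition.name,
            state_from=transition.state_from,
            state_to=transition.state_to,
        )
    g.graph["alpha"] = alpha
    prow = ptable.set_index("set_id")
    for pid in enriched_ids:
        g.add_node(
            pid,
            name=collection[pid].name,
            T=float(prow.at[pid, "statistic"]),
            q=float(prow.at[pid, "q"]),
        )
    if not enriched_ids:
        return g

    # step 2: crosstalk among the perturbed pathways only
    regions = crosstalk_regions(collection, enriched_ids, cfg.min_region_size)
    if not regions:
        return g

    # step 3: perturbed crosstalk regions (a separate BH family)
    region_sets = [("%s|%s" % r.pair, r.genes) for r in regions]
    rtable = enrich(
        expr, region_sets, alpha, min_set_size=cfg.min_region_test_size, **common
    )
    logger.info(
        "regions: %d candidate, %d tested, %d enriched at q<%g",
        len(regions), int(rtable["tested"].sum()), int(rtable["enriched"].sum()), alpha,
    )

    # step 4: network integration
    rrow = rtable.set_index("set_id")
    for region in regions:
        key = "%s|%s" % region.pair
        if not bool(rrow.at[key, "enriched"]):
            continue
        a, b = region.pair
        g.add_edge(
            a, b,
            region_size=len(region.genes),
            T=float(rrow.at[key, "statistic"]),
            q=float(rrow.at[key, "q"]),
            jaccard=jaccard(collection[a].genes, collection[b].genes),
        )
    return g


# GML restricts attribute keys to alphanumerics; map pythonic names through.
_TO_GML = {"region_size": "regionSize", "state_from": "stateFrom", "state_to": "stateTo"}
_FROM_GML = {v: k for k, v in _TO_GML.items()}


def _rename(attrs: dict, table: dict) -> dict:
    return {table.get(k, k): v for k, v in attrs.items()}


def write_gml(graph: nx.Graph, path: str | Path) -> None:
    """Write a network as GML: integer node ``id``, pathway id as ``label``,
    declared attributes on nodes and edges; isolated nodes preserved."""
    out = nx.Graph()
    out.graph.update(_rename(graph.graph, _TO_GML))
    for node, attrs in graph.nodes(data=True):
        out.add_node(node, **_rename(attrs, _TO_GML))
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(u, v, **_rename(attrs, _TO_GML))
    nx.write_gml(out, str(path))


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML network, keying nodes by their ``label`` (pathway id).

    Attribute-free GML (plain topology) is accepted.
    """
    try:
        raw = nx.read_gml(str(path), label="label")
    except nx.NetworkXError as exc:
        raise ValueError(f"malformed GML in {path}: {exc}") from exc
    g = nx.Graph()
    g.graph.update(_rename(raw.graph, _FROM_GML))
    for node, attrs in raw.nodes(data=True):
        g.add_node(node, **_rename(attrs, _FROM_GML))
    for u, v, attrs in raw.edges(data=True):
        g.add_edge(u, v, **_rename(attrs, _FROM_GML))
    return g


def _edge_set(g: nx.Graph) -> set[tuple[str, str]]:
    return {tuple(sorted((str(u), str(v)))) for u, v in g.edges()}


def compare_networks(g1: nx.Graph, g2: nx.Graph) -> tuple[float, float]:
    """Node and edge Jaccard indices between two networks.

    Edges are canonicalized as sorted pairs.  When both edge sets are empty
    the edge index is reported as 1.0 (identical empty sets).
    """
    n1, n2 = set(map(str, g1.nodes)), set(map(str, g2.nodes))
    if not n1 and not n2:
        raise ValueError("both networks are empty; similarity undefined")
    node_j = jaccard(n1, n2)
    e1, e2 = _edge_set(g1), _edge_set(g2)
    edge_j = 1.0 if not (e1 | e2) else jaccard_pairs(e1, e2)
    return node_j, edge_j


def jaccard_pairs(a: set, b: set) -> float:
    return len(a & b) / len(a | b)
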