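"""Two null models for PXPN structure.

*Rewiring null*: resample the network's edges among all biologically
possible crosstalks (node pairs with intersecting gene sets), with
probability proportional to the pairwise Jaccard index, conserving the node
set and the edge count.  An ensemble of rewired replicates yields a null
mean/sd per topological metric and a Z-test for the observed value.

*Label-shuffle null*: permute the gene labels of the expression matrix and
rerun the whole PXPN pipeline.  Real data should yield structured networks;
shuffled data should yield mostly empty or trivially structured ones
(single edges, stars, cliques), which this module counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .enrichment import ExpressionMatrix
from .netstats import topology_summary
from .network import PxpnConfig, build_pxpn
from .pathways import PathwayCollection, jaccard

__all__ = [
    "rewire_network",
    "rewire_ensemble",
    "ztest",
    "shuffle_gene_labels",
    "classify_structure",
    "shuffle_ensemble",
    "EnsembleSummary",
    "ShuffleSummary",
    "STRUCTURE_CLASSES",
]

STRUCTURE_CLASSES = ("empty", "single_edge", "clique", "star", "other")


def _candidate_pairs(graph, collection, min_region_size):
    nodes = sorted(graph.nodes)
    pairs, weights = [], []
    for i, a in enumerate(nodes):
        ga = collection[a].genes
        for b in nodes[i + 1:]:
            shared = ga & collection[b].genes
            if len(shared) >= min_region_size:
                pairs.append((a, b))
                weights.append(jaccard(ga, collection[b].genes))
    return pairs, np.asarray(weights, dtype=float)


def rewire_network(
    graph: nx.Graph,
    collection: PathwayCollection,
    rng: np.random.Generator,
    min_region_size: int = 1,
) -> nx.Graph:
    """One rewired replicate: same nodes, same edge count, edges resampled.

    Edges are drawn without replacement from the candidate pairs (node pairs
    with intersecting gene sets) with probability proportional to the
    pairwise Jaccard index, so heavily overlapping pathways reconnect more
    often.  No self-loops or multi-edges can arise.
    """
    e = graph.number_of_edges()
    if e == 0:
        raise ValueError("cannot rewire a graph with no edges")
    pairs, weights = _candidate_pairs(graph, collection, min_region_size)
    if e > len(pairs):
        raise ValueError(
            f"edge count {e} exceeds the {len(pairs)} candidate crosstalk pairs"
        )
    chosen = rng.choice(len(pairs), size=e, replace=False, p=weights / weights.sum())
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    for idx in chosen:
        a, b = pairs[idx]
        out.add_edge(
            a, b,
            region_size=len(collection[a].genes & collection[b].genes),
            jaccard=float(weights[idx]),
        )
    return out


def ztest(observed: float, values) -> tuple[float | None, float | None]:
    """Z-score of an observed value against an ensemble (sample sd, n-1) and
    its two-sided normal p.  Returns (None, None) when the ensemble sd is 0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 ensemble values")
    sd = values.std(ddof=1)
    if sd == 0:
        return None, None
    z = (observed - values.mean()) / sd
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class MetricZ:
    observed: float | None
    null_mean: float | None
    null_sd: float | None
    z: float | None
    p_two_sided: float | None


@dataclass
class EnsembleSummary:
    """Observed vs rewiring-null statistics per topological metric."""

    metrics: dict[str, MetricZ]
    ensemble_size: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "ensemble_size": self.ensemble_size,
            "seed": self.seed,
            "metrics": {k: vars(v) for k, v in self.metrics.items()},
        }


#: TopologySummary fields compared against the rewiring null
_METRICS = (
    "nodes",
    "edges",
    "density",
    "specific_density",
    "average_degree",
    "clustering_coefficient",
    "average_shortest_path",
    "connected_components",
    "single_nodes",
)


def rewire_ensemble(
    graph: nx.Graph,
    collection: PathwayCollection,
    n: int = 5000,
    seed: int = 0,
    min_region_size: int = 1,
) -> EnsembleSummary:
    """Generate ``n`` rewired replicates and Z-test each topological metric.

    Node and edge counts are conserved by construction, so their null sd is
    0 and their z is reported as None.  Replicate RNG streams are spawned
    from the master seed by index, making the ensemble reproducible.
    """
    observed = topology_summary(graph, collection, min_region_size).to_dict()
    streams = np.random.SeedSequence(seed).spawn(n)
    samples: dict[str, list[float]] = {m: [] for m in _METRICS}
    for ss in streams:
        rep = rewire_network(graph, collection, np.random.default_rng(ss), min_region_size)
        summary = topology_summary(rep, collection, min_region_size).to_dict()
        for m in _METRICS:
            v = summary[m]
            samples[m].append(math.nan if v is None else float(v))
    metrics = {}
    for m in _METRICS:
        vals = np.asarray(samples[m], dtype=float)
        vals = vals[np.isfinite(vals)]
        obs = observed[m]
        if obs is None or len(vals) < 2:
            metrics[m] = MetricZ(obs, None, None, None, None)
            continue
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        z, p = ztest(obs, vals) if sd > 0 else (None, None)
        metrics[m] = MetricZ(float(obs), mean, sd, z, p)
    return EnsembleSummary(metrics=metrics, ensemble_size=n, seed=seed)


def shuffle_gene_labels(expr: ExpressionMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    """Permute the gene (row) labels uniformly at random; values untouched."""
    perm = rng.permutation(len(expr.genes))
    shuffled = expr.values.copy()
    shuffled.index = expr.genes[perm]
    return expr.with_values(shuffled)


def classify_structure(graph: nx.Graph) -> str:
    """Classify a network as empty / single_edge / clique / star / other.

    Precedence is fixed (first match wins): a triangle is a clique, not a
    star; a lone edge is its own class.  Isolated nodes are ignored — the
    classification describes the edge-bearing core.
    """
    e = graph.number_of_edges()
    if e == 0:
        return "empty"
    if e == 1:
        return "single_edge"
    core = [node for node, deg in graph.degree() if deg > 0]
    k = len(core)
    if k >= 3 and e == k * (k - 1) // 2 and nx.density(graph.subgraph(core)) == 1.0:
        return "clique"
    if e >= 3:
        hubs = set(core)
        for u, v in graph.edges():
            hubs &= {u, v}
            if not hubs:
                break
        if hubs:
            return "star"
    return "other"


@dataclass
class ShuffleSummary:
    """Structure-class counts over a label-shuffle null ensemble."""

    counts: dict[str, int]
    more_than_one_edge: int
    n: int
    seed: int
    empty_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.empty_fraction = self.counts.get("empty", 0) / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "more_than_one_edge": self.more_than_one_edge,
            "n": self.n,
            "seed": self.seed,
            "empty_fraction": self.empty_fraction,
        }


def shuffle_ensemble(
    expr: ExpressionMatrix,
    collection: PathwayCollection,
    n: int = 1500,
    alpha: float = 0.05,
    seed: int = 0,
    config: PxpnConfig | None = None,
) -> ShuffleSummary:
    """Run the full PXPN pipeline on ``n`` label-shuffled datasets.

    Each replicate shuffles the gene labels, rebuilds the PXPN, and
    classifies its structure; counts per class and the number of replicates
    with more than one edge are returned.
    """
    streams = np.random.SeedSequence(seed).spawn(n)
    counts = {c: 0 for c in STRUCTURE_CLASSES}
    multi_edge = 0
    for ss in streams:
        shuffled = shuffle_gene_labels(expr, np.random.default_rng(ss))
        g = build_pxpn(shuffled, collection, alpha=alpha, config=config)
        counts[classify_structure(g)] += 1
        if g.number_of_edges() > 1:
            multi_edge += 1
    return ShuffleSummary(counts=counts, more_than_one_edge=multi_edge, n=n, seed=seed)
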