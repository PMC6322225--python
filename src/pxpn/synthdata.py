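"""Synthetic pathway collections and two-group expression data with planted
perturbations, plus recovery scoring.

The generator emulates what the PXPN pipeline consumes: a pathway
collection with controlled pairwise overlaps, and a genes x samples
abundance matrix for two groups of biological replicates.  Abundances are
Gaussian around a common baseline; in the target group, *affected* genes
are mean-shifted by ``effect_size`` noise standard deviations.  Affected
genes are the exclusive genes of the planted perturbed pathways plus the
shared genes of the planted perturbed crosstalk regions — so pathway-level
and edge-level ground truth stay unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import ExpressionMatrix
from .pathways import Pathway, PathwayCollection

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "make_collection",
    "affected_genes",
    "simulate_expression",
    "recovery_metrics",
    "default_scenario",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulation.

    Defaults mirror a small two-condition RNA profiling design: 6 biological
    replicates per group, 10 pathways of 20 genes with 4-gene overlaps where
    planned, 200 pathway-free background genes, and a 3-sigma mean shift for
    affected genes.
    """

    n_pathways: int = 10
    genes_per_pathway: int = 20
    overlap_size: int = 4
    n_background_genes: int = 200
    samples_per_group: int = 6
    effect_size: float = 3.0  # mean shift in units of noise sd
    noise_sd: float = 1.0
    baseline_mean: float = 10.0
    group_a: str = "A"
    group_b: str = "B"

    def __post_init__(self) -> None:
        if self.overlap_size >= self.genes_per_pathway:
            raise ValueError("overlap_size must be smaller than genes_per_pathway")
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: which pathways and which crosstalk regions are
    perturbed."""

    perturbed_pathways: frozenset[str]
    perturbed_regions: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.perturbed_regions:
            if a not in self.perturbed_pathways or b not in self.perturbed_pathways:
                raise ValueError(
                    f"region ({a}, {b}) is not a pair of perturbed pathways"
                )

    @staticmethod
    def region_key(a: str, b: str) -> tuple[str, str]:
        return tuple(sorted((a, b)))  # type: ignore[return-value]


def make_collection(
    params: SimulationParams,
    pair_plan: list[tuple[str, str]] | None = None,
    seed: int | None = None,
) -> PathwayCollection:
    """Build a collection with exactly the planned pairwise overlaps.

    Pathway ids are ``P01..Pnn``.  Each planned pair shares exactly
    ``overlap_size`` genes (distinct per pair, so no triple overlaps);
    unplanned pairs are disjoint.  The seed only permutes the gene-id pool,
    so the overlap structure is identical across seeds.
    """
    ids = [f"P{i:02d}" for i in range(1, params.n_pathways + 1)]
    known = set(ids)
    plan = [SyntheticTruth.region_key(a, b) for a, b in (pair_plan or [])]
    if len(plan) != len(set(plan)):
        raise ValueError("pair_plan contains duplicate pairs")
    for a, b in plan:
        if a not in known or b not in known or a == b:
            raise ValueError(f"invalid planned pair ({a}, {b})")
    shared_load = {pid: 0 for pid in ids}
    for a, b in plan:
        shared_load[a] += params.overlap_size
        shared_load[b] += params.overlap_size
    for pid, load in shared_load.items():
        if load >= params.genes_per_pathway:
            raise ValueError(
                f"pathway {pid} would need {load} shared genes but holds only "
                f"{params.genes_per_pathway}"
            )
    total = sum(
        params.genes_per_pathway - shared_load[pid] for pid in ids
    ) + params.overlap_size * len(plan)
    pool = [f"g{i:05d}" for i in range(total)]
    if seed is not None:
        pool = [pool[i] for i in np.random.default_rng(seed).permutation(total)]
    cursor = 0

    def take(k: int) -> frozenset[str]:
        nonlocal cursor
        out = frozenset(pool[cursor: cursor + k])
        cursor += k
        return out

    members: dict[str, set[str]] = {pid: set() for pid in ids}
    for a, b in sorted(plan):
        shared = take(params.overlap_size)
        members[a] |= shared
        members[b] |= shared
    pathways = []
    for pid in ids:
        members[pid] |= take(params.genes_per_pathway - len(members[pid]))
        pathways.append(Pathway(id=pid, name=f"synthetic pathway {pid}", genes=frozenset(members[pid])))
    return PathwayCollection(pathways)


def affected_genes(collection: PathwayCollection, truth: SyntheticTruth) -> frozenset[str]:
    """Genes the planted perturbation shifts: exclusive genes of perturbed
    pathways plus the shared genes of perturbed regions.

    A gene shared between pathways is shifted only when its region is
    planted, keeping edge-level ground truth unambiguous.
    """
    counts: dict[str, int] = {}
    for p in collection:
        for gene in p.genes:
            counts[gene] = counts.get(gene, 0) + 1
    out: set[str] = set()
    for pid in truth.perturbed_pathways:
        if pid not in collection:
            raise KeyError(f"perturbed pathway {pid!r} not in collection")
        out |= {g for g in collection[pid].genes if counts[g] == 1}
    for a, b in truth.perturbed_regions:
        shared = collection[a].genes & collection[b].genes
        if not shared:
            raise ValueError(f"planted region ({a}, {b}) has no shared genes")
        out |= shared
    return frozenset(out)


def simulate_expression(
    collection: PathwayCollection,
    truth: SyntheticTruth,
    params: SimulationParams,
    seed: int,
) -> ExpressionMatrix:
    """Simulate the genes x samples matrix for the planted scenario.

    Every gene is Normal(baseline_mean, noise_sd^2) in group A; affected
    genes gain ``effect_size * noise_sd`` in group B.  Values are floored at
    0 to stay abundance-like.  Bitwise reproducible given (params, seed).
    """
    affected = affected_genes(collection, truth)
    genes = sorted(collection.universe) + [
        f"bg{i:05d}" for i in range(params.n_background_genes)
    ]
    spg = params.samples_per_group
    samples = [f"{params.group_a}{i+1}" for i in range(spg)] + [
        f"{params.group_b}{i+1}" for i in range(spg)
    ]
    design = {s: (params.group_a if i < spg else params.group_b) for i, s in enumerate(samples)}
    rng = np.random.default_rng(seed)
    values = rng.normal(params.baseline_mean, params.noise_sd, size=(len(genes), 2 * spg))
    shift_rows = np.array([g in affected for g in genes])
    values[np.ix_(shift_rows, np.arange(spg, 2 * spg))] += params.effect_size * params.noise_sd
    values = np.clip(values, 0.0, None)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(df, design, params.group_a, params.group_b)


def recovery_metrics(
    graph: nx.Graph,
    truth: SyntheticTruth,
    collection: PathwayCollection,
    min_region_size: int = 1,
) -> dict[str, float | None]:
    """Score a recovered PXPN against the planted truth.

    Node sensitivity/specificity are over planted vs non-planted pathways;
    edge metrics are over planted region pairs vs all candidate (overlapping)
    pairs among the planted pathways.  A metric with an empty denominator is
    None.
    """
    recovered_nodes = set(graph.nodes)
    planted = set(truth.perturbed_pathways)
    nonplanted = set(collection.ids) - planted
    planted_edges = {SyntheticTruth.region_key(a, b) for a, b in truth.perturbed_regions}
    candidates = set()
    for a in planted:
        for b in planted:
            if a < b and len(collection[a].genes & collection[b].genes) >= min_region_size:
                candidates.add((a, b))
    recovered_edges = {SyntheticTruth.region_key(u, v) for u, v in graph.edges()}
    neg_edges = candidates - planted_edges

    def ratio(hits: int, total: int) -> float | None:
        return hits / total if total else None

    return {
        "node_sensitivity": ratio(len(recovered_nodes & planted), len(planted)),
        "node_specificity": ratio(len(nonplanted - recovered_nodes), len(nonplanted)),
        "edge_sensitivity": ratio(len(recovered_edges & planted_edges), len(planted_edges)),
        "edge_specificity": ratio(len(neg_edges - recovered_edges), len(neg_edges)),
    }


def default_scenario(
    params: SimulationParams | None = None,
) -> tuple[SimulationParams, list[tuple[str, str]], SyntheticTruth]:
    """The stock planted scenario used by tests and examples.

    Ten pathways; P01-P02-P03 overlap pairwise, with the P01-P02 and
    P02-P03 regions planted as perturbed but the P01-P03 region left
    unperturbed (a planted true-negative edge); P04-P05 and P06-P07 overlap
    but are entirely unperturbed.
    """
    params = params or SimulationParams()
    if params.n_pathways < 7:
        raise ValueError("default scenario needs at least 7 pathways")
    plan = [("P01", "P02"), ("P02", "P03"), ("P01", "P03"), ("P04", "P05"), ("P06", "P07")]
    truth = SyntheticTruth(
        perturbed_pathways=frozenset({"P01", "P02", "P03"}),
        perturbed_regions=frozenset({("P01", "P02"), ("P02", "P03")}),
    )
    return params, plan, truth
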