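"""Pathway collections, crosstalk regions, and the full pathway crosstalk network (PXN).

A pathway is modeled purely by gene membership: a named set of gene
identifiers.  Two pathways *crosstalk* when their gene sets intersect; the
intersection is the crosstalk region.  The PXN is the graph over every
pathway in a collection with an edge for each overlapping pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Pathway",
    "PathwayCollection",
    "CrosstalkRegion",
    "read_gmt",
    "write_gmt",
    "jaccard",
    "crosstalk_regions",
    "build_pxn",
]


class GmtParseError(ValueError):
    """Raised when a GMT file cannot be parsed."""


def _normalize(symbol: str, mode: str) -> str:
    if mode == "exact":
        return symbol
    if mode == "casefold":
        return symbol.casefold()
    raise ValueError(f"unknown normalization mode: {mode!r}")


@dataclass(frozen=True)
class Pathway:
    """A named gene set."""

    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene set")


@dataclass(frozen=True)
class CrosstalkRegion:
    """Genes shared by an unordered pair of pathways."""

    pair: tuple[str, str]  # sorted pathway ids
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("crosstalk region requires two distinct pathways")
        if not self.genes:
            raise ValueError("crosstalk region has an empty gene set")


class PathwayCollection:
    """An ordered collection of uniquely identified pathways.

    The *universe* is the union of all member gene sets; it defines which
    genes can ever participate in a crosstalk region.
    """

    def __init__(self, pathways: Iterable[Pathway]):
        self.pathways: list[Pathway] = list(pathways)
        self._by_id: dict[str, Pathway] = {}
        for p in self.pathways:
            if p.id in self._by_id:
                raise ValueError(f"duplicate pathway id: {p.id!r}")
            self._by_id[p.id] = p

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)

    def gene_sets(self) -> list[tuple[str, frozenset[str]]]:
        """(id, genes) pairs, e.g. for enrichment."""
        return [(p.id, p.genes) for p in self.pathways]


def read_gmt(path: str | Path, normalization: str = "exact") -> PathwayCollection:
    """Read a GMT gene-set file (tab-separated: id, description, genes...).

    Lines starting with ``#`` and blank lines are skipped.  Duplicate gene
    tokens within a line are deduplicated; a line with fewer than three
    fields or no genes is a parse error naming the offending line.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            genes = frozenset(
                _normalize(tok, normalization) for tok in fields[2:] if tok.strip()
            )
            if not genes:
                raise GmtParseError(f"{path.name}:{lineno}: gene set {set_id!r} is empty")
            pathways.append(Pathway(id=set_id, name=description, genes=genes))
    try:
        return PathwayCollection(pathways)
    except ValueError as exc:
        raise GmtParseError(f"{path.name}: {exc}") from exc


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes are sorted for determinism."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in collection:
            fh.write("\t".join([p.id, p.name, *sorted(p.genes)]) + "\n")


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |a∩b| / |a∪b| of two gene sets.

    Undefined (raises) when both sets are empty.
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def crosstalk_regions(
    collection: PathwayCollection,
    ids: Sequence[str] | None = None,
    min_region_size: int = 1,
) -> list[CrosstalkRegion]:
    """All crosstalk regions among the given pathways.

    One region per unordered pair whose intersection holds at least
    ``min_region_size`` genes, in sorted pair order.
    """
    if ids is None:
        ids = collection.ids
    for pid in ids:
        if pid not in collection:
            raise KeyError(f"unknown pathway id: {pid!r}")
    regions: list[CrosstalkRegion] = []
    for a, b in itertools.combinations(sorted(set(ids)), 2):
        shared = collection[a].genes & collection[b].genes
        if len(shared) >= min_region_size and shared:
            regions.append(CrosstalkRegion(pair=(a, b), genes=frozenset(shared)))
    return regions


def build_pxn(collection: PathwayCollection, min_region_size: int = 1) -> nx.Graph:
    """Build the pathway crosstalk network over an entire collection.

    Nodes are pathway ids; an edge joins every pair with a non-empty
    intersection (of size >= ``min_region_size``), annotated with the region
    size and the Jaccard index of the parent gene sets.
    """
    if len(collection) == 0:
        raise ValueError("empty pathway collection")
    g = nx.Graph()
    for p in collection:
        g.add_node(p.id, name=p.name, size=len(p.genes))
    for region in crosstalk_regions(collection, min_region_size=min_region_size):
        a, b = region.pair
        g.add_edge(
            a,
            b,
            region_size=len(region.genes),
            jaccard=jaccard(collection[a].genes, collection[b].genes),
        )
    return g
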