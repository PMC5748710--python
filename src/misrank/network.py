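"""Core containers: weighted PPI network, gene sets, and disease-class catalogs.

The network is an undirected graph over protein-ID strings whose edges carry a
single integer confidence score (the STRING "combined score" convention: higher
means the interaction is more likely, typically on [150, 999]).  All downstream
statistics depend only on ``S(p1, p2)``, the score of the unordered pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import DataQualityWarning, ValidationError

__all__ = ["GeneSet", "WeightedPPINetwork", "DiseaseClassCatalog"]


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique protein/gene IDs.

    Order is first-occurrence order of the source (file, catalog row, or random
    draw); it fixes the order of per-gene result records.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(
                f"gene set {self.name!r} contains duplicate members"
            )

    @classmethod
    def from_iterable(cls, name: str, ids: Iterable[str]) -> tuple["GeneSet", int]:
        """Build a set keeping first occurrences; returns (set, n_duplicates)."""
        seen: dict[str, None] = {}
        n_dup = 0
        for gid in ids:
            if gid in seen:
                n_dup += 1
            else:
                seen[gid] = None
        return cls(name, tuple(seen)), n_dup

    @cached_property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, gid: object) -> bool:
        return gid in self.member_set


class WeightedPPINetwork:
    """Undirected protein–protein interaction network with integer edge scores.

    Backed by a :class:`networkx.Graph`; each edge carries a ``score``
    attribute.  Self-loops are rejected and each unordered pair is stored once,
    so ``score(a, b) == score(b, a)`` by construction.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self._g = graph if graph is not None else nx.Graph()
        #: number of symmetric duplicate records collapsed by the loader
        self.duplicates_collapsed: int = 0

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "WeightedPPINetwork":
        net = cls()
        for a, b, s in edges:
            net.add_edge(a, b, s)
        return net

    def add_edge(self, a: str, b: str, score: int) -> None:
        if a == b:
            raise ValidationError(f"self-loop on node {a!r} is not allowed")
        score = int(score)
        existing = self._g.get_edge_data(a, b)
        if existing is not None and existing["score"] != score:
            raise ValidationError(
                f"conflicting scores for pair ({a!r}, {b!r}): "
                f"{existing['score']} vs {score}"
            )
        self._g.add_edge(a, b, score=score)

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> Iterable[str]:
        return self._g.nodes

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: object) -> bool:
        return node in self._g

    def score(self, a: str, b: str) -> int | None:
        """Score of the unordered pair (a, b), or None if no such edge."""
        data = self._g.get_edge_data(a, b)
        return None if data is None else data["score"]

    def neighbor_scores(self, node: str) -> Mapping[str, int]:
        """Mapping neighbor -> edge score for one node."""
        if node not in self._g:
            raise ValidationError(f"node {node!r} is not in the network")
        return {nbr: d["score"] for nbr, d in self._g[node].items()}

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Edges as (a, b, score) with a < b, in deterministic sorted order."""
        for a, b, d in sorted(
            (min(u, v), max(u, v), d) for u, v, d in self._g.edges(data=True)
        ):
            yield a, b, d["score"]

    def copy(self) -> "WeightedPPINetwork":
        clone = WeightedPPINetwork(self._g.copy())
        clone.duplicates_collapsed = self.duplicates_collapsed
        return clone

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedPPINetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and list(self.edges()) == list(
            other.edges()
        )

    def __repr__(self) -> str:
        return f"WeightedPPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class DiseaseClassCatalog:
    """Ordered mapping of disease-class name -> member :class:`GeneSet`.

    A gene may belong to several classes (comorbidity genes do), but only once
    to a given class.  Insertion order is the first-seen order of the source
    catalog and is preserved in all outputs.
    """

    classes: dict[str, GeneSet] = field(default_factory=dict)
    provenance: str = ""

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.classes:
            raise ValidationError(f"duplicate class name {gene_set.name!r}")
        self.classes[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.classes.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.classes[name]

    def __contains__(self, name: object) -> bool:
        return name in self.classes

    def names(self) -> list[str]:
        return list(self.classes)

    def warn_if_empty(self) -> None:
        for name, gs in self.classes.items():
            if not gs.members:
                warnings.warn(
                    f"class {name!r} has no members", DataQualityWarning, stacklevel=2
                )
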