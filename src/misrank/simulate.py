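"""Synthetic desk-scale studies with known planted association strengths.

The generator emulates the statistical skeleton of a STRING-style analysis: a
sparse Erdős–Rényi background network whose edges carry integer confidence
scores, a query gene set, and disease classes.  A class's association with the
query set is *planted*: each class gene independently receives, with
probability ``planting_strength``, one high-score edge to a random query
member.  Strength 0 gives a pure-null class; strength 1 with planted score 999
forces p = 0 for every gene under the strict-greater exceedance rule.  The
ground truth (strength per class) is returned alongside the study so recovery
can be benchmarked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ValidationError
from .network import DiseaseClassCatalog, GeneSet, WeightedPPINetwork

__all__ = [
    "ClassSpec",
    "SyntheticStudySpec",
    "SyntheticStudy",
    "generate_background_network",
    "plant_class_association",
    "generate_study",
]

SCORE_SAMPLERS = ("uniform", "skewed")


def _draw_scores(
    rng: np.random.Generator, size: int, sampler: str, low: int, high: int
) -> np.ndarray:
    """Integer scores on [low, high]; 'skewed' mimics STRING's low-score mass."""
    if sampler == "uniform":
        return rng.integers(low, high + 1, size=size)
    if sampler == "skewed":
        # Beta(1, 4) pushes ~80% of the mass into the lower half of the range,
        # stressing tie handling at common low scores.
        frac = rng.beta(1.0, 4.0, size=size)
        return low + np.minimum((frac * (high - low + 1)).astype(np.int64), high - low)
    raise ValidationError(f"unknown score sampler {sampler!r}; use one of {SCORE_SAMPLERS}")


@dataclass(frozen=True)
class ClassSpec:
    name: str
    n_genes: int
    planting_strength: float
    planted_score_low: int = 980
    planted_score_high: int = 999

    def __post_init__(self) -> None:
        if not 0.0 <= self.planting_strength <= 1.0:
            raise ValidationError("planting_strength must be in [0, 1]")
        if self.planted_score_low > self.planted_score_high:
            raise ValidationError("planted score range is inverted")


@dataclass(frozen=True)
class SyntheticStudySpec:
    n_proteins: int
    edge_probability: float
    query_size: int
    classes: tuple[ClassSpec, ...]
    seed: int = 0
    score_sampler: str = "uniform"
    score_low: int = 150
    score_high: int = 999
    disjoint: bool = True

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValidationError("need at least 2 proteins")
        if not 0.0 < self.edge_probability < 1.0:
            raise ValidationError("edge_probability must be in (0, 1)")
        if self.query_size < 1:
            raise ValidationError("query_size must be >= 1")
        total = self.query_size + sum(c.n_genes for c in self.classes)
        if self.disjoint and total > self.n_proteins:
            raise ValidationError(
                f"disjoint layout infeasible: query + classes need {total} nodes, "
                f"network has {self.n_proteins}"
            )
        for c in self.classes:
            if not (self.score_low <= c.planted_score_low
                    and c.planted_score_high <= self.score_high):
                raise ValidationError(
                    f"class {c.name!r}: planted score range outside global bounds"
                )


@dataclass
class SyntheticStudy:
    network: WeightedPPINetwork
    query_set: GeneSet
    catalog: DiseaseClassCatalog
    truth: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit network/query/catalog/truth files in the dialects the readers use."""
        from . import io as mio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": out / "network.links.txt",
            "query": out / "query_genes.txt",
            "catalog": out / "disease_classes.tsv",
            "truth": out / "truth.json",
        }
        mio.write_string_links(self.network, paths["network"])
        mio.write_gene_set(self.query_set, paths["query"])
        mio.write_class_catalog(self.catalog, paths["catalog"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _node_name(i: int) -> str:
    return f"P{i:06d}"


def generate_background_network(
    n_proteins: int,
    edge_probability: float,
    score_sampler: str = "uniform",
    seed: int = 0,
    *,
    score_low: int = 150,
    score_high: int = 999,
) -> WeightedPPINetwork:
    """Erdős–Rényi G(n, p) network with i.i.d. integer edge scores."""
    if n_proteins < 2:
        raise ValidationError("need at least 2 proteins")
    if not 0.0 < edge_probability < 1.0:
        raise ValidationError("edge_probability must be in (0, 1)")
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_proteins, edge_probability, seed=int(rng.integers(2**31)))
    edge_list = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    scores = _draw_scores(rng, len(edge_list), score_sampler, score_low, score_high)
    net = WeightedPPINetwork()
    for i in range(n_proteins):
        net.add_node(_node_name(i))
    for (u, v), s in zip(edge_list, scores):
        net.add_edge(_node_name(u), _node_name(v), int(s))
    return net


def plant_class_association(
    network: WeightedPPINetwork,
    class_genes: GeneSet,
    query_set: GeneSet,
    strength: float,
    score_low: int,
    score_high: int,
    seed: int,
) -> WeightedPPINetwork:
    """Give each class gene, with probability ``strength``, one high-score edge
    to a uniformly chosen query member.  Planted edges overwrite any existing
    score for that pair; everything else is untouched.  Returns a new network.
    """
    if len(query_set) == 0:
        raise ValidationError("query set is empty")
    if not 0.0 <= strength <= 1.0:
        raise ValidationError("strength must be in [0, 1]")
    for gid in list(class_genes) + list(query_set):
        if gid not in network:
            raise ValidationError(f"gene {gid!r} is not a network node")
    rng = np.random.default_rng(seed)
    planted = network.copy()
    for gene in class_genes:
        if rng.random() >= strength:
            continue
        partners = [m for m in query_set if m != gene]
        if not partners:
            continue
        partner = partners[int(rng.integers(len(partners)))]
        score = int(rng.integers(score_low, score_high + 1))
        # overwrite: bypass the conflict check, this is a deliberate rewrite
        planted._g.add_edge(gene, partner, score=score)
    return planted


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Compose background network + planted classes into a full study fixture.

    With ``disjoint=True`` the query set and every class occupy consecutive
    non-overlapping node blocks; otherwise class genes are drawn uniformly
    (without replacement within a class) from the non-query nodes, so classes
    may overlap each other.
    """
    rng = np.random.default_rng(spec.seed)
    network = generate_background_network(
        spec.n_proteins,
        spec.edge_probability,
        spec.score_sampler,
        seed=int(rng.integers(2**31)),
        score_low=spec.score_low,
        score_high=spec.score_high,
    )
    nodes = sorted(network.nodes)
    query = GeneSet("query", tuple(nodes[: spec.query_size]))
    non_query = nodes[spec.query_size:]

    catalog = DiseaseClassCatalog(provenance="synthetic")
    cursor = spec.query_size
    for cls in spec.classes:
        if spec.disjoint:
            members = tuple(nodes[cursor : cursor + cls.n_genes])
            cursor += cls.n_genes
        else:
            if cls.n_genes > len(non_query):
                raise ValidationError(
                    f"class {cls.name!r} needs {cls.n_genes} genes, only "
                    f"{len(non_query)} non-query nodes available"
                )
            draw = rng.choice(len(non_query), size=cls.n_genes, replace=False)
            members = tuple(non_query[j] for j in draw)
        catalog.add(GeneSet(cls.name, members))

    truth: dict[str, float] = {}
    for cls in spec.classes:
        network = plant_class_association(
            network,
            catalog[cls.name],
            query,
            cls.planting_strength,
            cls.planted_score_low,
            cls.planted_score_high,
            seed=int(rng.integers(2**31)),
        )
        truth[cls.name] = cls.planting_strength
    return SyntheticStudy(network=network, query_set=query, catalog=catalog, truth=truth)
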