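"""Maximum interaction scores and permutation-calibrated p-values.

For a disease gene *g* and a query gene set *Q* on a weighted PPI network, the
maximum interaction score is

    MIS(g) = max{ S(g, g') : g' in Q, g' != g }        (0 if no edge exists)

Because a single high-confidence edge drives MIS, its raw value is confounded
by hub effects and network noise: a promiscuous gene scores high against *any*
set.  MIS is therefore calibrated against random gene sets D_1 ... D_n of the
same size as Q, drawn uniformly from the network's node universe:

    MIS_i(g) = max{ S(g, g') : g' in D_i },   Λ = #{ i : MIS_i(g) > MIS(g) }
    p_value(g) = Λ / n

The comparison is strictly greater, so p = 0 is attainable and ties between a
random-set MIS and the query MIS do not count against the gene; this is
anti-conservative relative to the (Λ+1)/(n+1) convention and is noted in the
docs.  One shared random-set collection is reused for every gene and class in
a run, making p-values comparable across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .errors import DataQualityWarning, ValidationError
from .network import GeneSet, WeightedPPINetwork

__all__ = [
    "RandomSetCollection",
    "GeneAssociationRecord",
    "max_interaction_score",
    "sample_random_sets",
    "permutation_pvalue",
    "score_disease_class",
]


@dataclass
class RandomSetCollection:
    """The D_i: an ordered list of uniformly drawn node sets of equal size.

    ``universe`` is the sorted node universe the sets were drawn from; a
    boolean membership matrix (n_sets x n_universe) is cached for vectorized
    MIS computation.
    """

    sets: list[GeneSet]
    universe: tuple[str, ...]
    set_size: int
    seed: int
    membership: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValidationError("random-set collection is empty")
        for s in self.sets:
            if len(s) != self.set_size:
                raise ValidationError(
                    f"random set {s.name!r} has size {len(s)} != {self.set_size}"
                )

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @cached_property
    def node_index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.universe)}


@dataclass(frozen=True)
class GeneAssociationRecord:
    """Per-gene result: query MIS, exceedance count Λ, permutation p-value."""

    gene: str
    mis: int
    lambda_count: int
    p_value: float
    n_permutations: int


def max_interaction_score(
    gene: str, target_set: GeneSet, network: WeightedPPINetwork
) -> int:
    """MIS of ``gene`` against ``target_set``; 0 if no edge links them.

    The gene itself is excluded from the target set (a gene shared between the
    disease class and the query set must not match itself).
    """
    if gene not in network:
        raise ValidationError(f"gene {gene!r} is not a network node")
    if len(target_set) == 0:
        raise ValidationError("target set is empty")
    neighbors = network.neighbor_scores(gene)
    best = 0
    if len(neighbors) <= len(target_set):
        for nbr, s in neighbors.items():
            if nbr != gene and nbr in target_set and s > best:
                best = s
    else:
        for member in target_set:
            if member == gene:
                continue
            s = neighbors.get(member)
            if s is not None and s > best:
                best = s
    return best


def sample_random_sets(
    network: WeightedPPINetwork, set_size: int, n_sets: int, seed: int
) -> RandomSetCollection:
    """Draw ``n_sets`` uniform random node sets of ``set_size`` distinct nodes.

    The universe is every network node (query members included).  Draws are
    independent across sets and fully reproducible from ``seed``; the universe
    is sorted so the result does not depend on node-set iteration order.
    """
    universe = tuple(sorted(network.nodes))
    if set_size > len(universe):
        raise ValidationError(
            f"set_size {set_size} exceeds universe of {len(universe)} nodes"
        )
    if set_size < 1 or n_sets < 1:
        raise ValidationError("set_size and n_sets must be positive")
    rng = np.random.default_rng(seed)
    membership = np.zeros((n_sets, len(universe)), dtype=bool)
    sets: list[GeneSet] = []
    for i in range(n_sets):
        draw = rng.choice(len(universe), size=set_size, replace=False)
        membership[i, draw] = True
        sets.append(GeneSet(f"D{i + 1}", tuple(universe[j] for j in draw)))
    return RandomSetCollection(
        sets=sets, universe=universe, set_size=set_size, seed=seed,
        membership=membership,
    )


def random_set_mis(
    gene: str, random_sets: RandomSetCollection, network: WeightedPPINetwork
) -> np.ndarray:
    """Vector of MIS_i(gene) over every random set (0 where no edge exists)."""
    neighbors = network.neighbor_scores(gene)
    index = random_sets.node_index
    pairs = [
        (index[nbr], s) for nbr, s in neighbors.items() if nbr != gene and nbr in index
    ]
    if not pairs:
        return np.zeros(random_sets.n_sets, dtype=np.int64)
    idx = np.array([i for i, _ in pairs], dtype=np.intp)
    scores = np.array([s for _, s in pairs], dtype=np.int64)
    present = random_sets.membership[:, idx]  # (n_sets, degree)
    return np.where(present, scores[np.newaxis, :], 0).max(axis=1)


def permutation_pvalue(
    gene: str,
    query_mis: int,
    random_sets: RandomSetCollection,
    network: WeightedPPINetwork,
) -> GeneAssociationRecord:
    """Calibrate a precomputed query MIS against the random-set collection.

    Λ counts random sets whose MIS_i strictly exceeds ``query_mis``; the gene
    itself never contributes to MIS_i (it cannot be its own neighbor, and set
    membership of the gene is score-less by the no-self-loop invariant).
    """
    mis_i = random_set_mis(gene, random_sets, network)
    lam = int(np.count_nonzero(mis_i > query_mis))
    return GeneAssociationRecord(
        gene=gene,
        mis=int(query_mis),
        lambda_count=lam,
        p_value=lam / random_sets.n_sets,
        n_permutations=random_sets.n_sets,
    )


def score_disease_class(
    class_genes: GeneSet,
    query_set: GeneSet,
    random_sets: RandomSetCollection,
    network: WeightedPPINetwork,
) -> list[GeneAssociationRecord]:
    """One association record per class gene, in catalog order.

    ``class_genes`` must already be network-filtered.  The same random-set
    collection is reused for every gene.
    """
    if len(class_genes) == 0:
        warnings.warn(
            f"class {class_genes.name!r} is empty after network filtering",
            DataQualityWarning,
            stacklevel=2,
        )
        return []
    records = []
    for gene in class_genes:
        mis = max_interaction_score(gene, query_set, network)
        records.append(permutation_pvalue(gene, mis, random_sets, network))
    return records
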