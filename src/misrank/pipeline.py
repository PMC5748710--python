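"""End-to-end study orchestration: load → filter → score → rank → write.

``score_study`` is the in-memory core (objects in, ranked results out);
``run_study`` wraps it with file I/O driven by a :class:`RunConfig` and writes
the per-gene table, class summary, PT-curve points, and run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping

import yaml

from . import io as mio
from .errors import MisrankError, ValidationError
from .network import DiseaseClassCatalog, GeneSet, WeightedPPINetwork
from .ranking import ClassAssociationResult, auc, pt_curve, rank_classes
from .scoring import sample_random_sets, score_disease_class

__all__ = ["RunConfig", "score_study", "run_study"]


@dataclass
class RunConfig:
    network: str
    query_set: str
    classes: str
    id_map: str | None = None
    n_permutations: int = 1000
    seed: int = 0
    min_score: int = 150
    max_score: int = 999
    report_cutoff: float = 0.05
    out_dir: str | None = None
    plot: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword overrides (CLI flags) win."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def score_study(
    network: WeightedPPINetwork,
    query_set: GeneSet,
    catalog: DiseaseClassCatalog,
    n_permutations: int,
    seed: int,
    mapping: Mapping[str, str] | None = None,
) -> list[ClassAssociationResult]:
    """Score and rank every catalog class against the query set.

    The query set and every class are filtered to network nodes through the
    same ``map_and_filter`` step; one random-set collection (size = filtered
    query size) is sampled once and reused throughout.  Returns results in
    rank order (AUC descending).
    """
    query, _dropped = mio.map_and_filter(query_set, mapping, network)
    if len(query) == 0:
        raise MisrankError("query set is empty after network filtering")
    random_sets = sample_random_sets(network, len(query), n_permutations, seed)
    results = []
    for gene_set in catalog:
        filtered, dropped = mio.map_and_filter(gene_set, mapping, network)
        records = score_disease_class(filtered, query, random_sets, network)
        p_values = [rec.p_value for rec in records]
        if p_values:
            curve = pt_curve(p_values, n_permutations=n_permutations)
            class_auc = auc(p_values)
        else:
            curve = None
            class_auc = float("nan")
        results.append(
            ClassAssociationResult(
                class_name=gene_set.name,
                records=tuple(records),
                curve=curve,
                auc=class_auc,
                n_genes_input=len(gene_set),
            )
        )
    return rank_classes(results)


def run_study(config: RunConfig) -> list[ClassAssociationResult]:
    """Execute a full study from files and write all result tables.

    Stages are named in error messages so a failing run points at its input.
    """
    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MisrankError as exc:
            raise MisrankError(f"[{name}] {exc}") from exc

    network = stage(
        "read-network", mio.read_string_links, config.network,
        config.min_score, config.max_score,
    )
    query_raw = stage("read-query", mio.read_gene_set, config.query_set, "query")
    catalog = stage("read-catalog", mio.read_class_catalog, config.classes)
    mapping = (
        stage("read-id-map", mio.read_id_map, config.id_map)
        if config.id_map
        else None
    )
    results = stage(
        "score", score_study, network, query_raw, catalog,
        config.n_permutations, config.seed, mapping,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_per_gene_table(results, out / "per_gene.tsv")
        mio.write_class_summary(results, out / "class_summary.tsv")
        mio.write_pt_curves(results, out / "pt_curves.tsv")
        significant = [
            dc_replace(
                res,
                records=tuple(
                    r for r in res.records if r.p_value < config.report_cutoff
                ),
            )
            for res in results
        ]
        mio.write_per_gene_table(significant, out / "per_gene_significant.tsv")
        query_filtered, query_dropped = mio.map_and_filter(query_raw, mapping, network)
        metadata = {
            "seed": config.seed,
            "n_permutations": config.n_permutations,
            "network": {
                "path": str(config.network),
                "n_nodes": network.n_nodes,
                "n_edges": network.n_edges,
                "duplicates_collapsed": network.duplicates_collapsed,
                "score_bounds": [config.min_score, config.max_score],
            },
            "query": {
                "n_input": len(query_raw),
                "n_in_network": len(query_filtered),
                "n_dropped": len(query_dropped),
            },
            "classes": {
                res.class_name: {
                    "n_input": res.n_genes_input,
                    "n_in_network": len(res.records),
                    "n_dropped": res.n_genes_input - len(res.records),
                    "auc": res.auc,
                    "rank": res.rank,
                }
                for res in results
            },
            "report_cutoff": config.report_cutoff,
        }
        mio.write_run_metadata(metadata, out / "run_metadata.json")
        if config.plot:
            from .ranking import plot_pt_curves

            plot_pt_curves(results, out / "pt_curves.png")
    return results
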