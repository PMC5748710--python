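"""Readers and writers for the pipeline's plain-text formats.

Input dialects
--------------
* Network: the STRING ``protein.links`` dialect — whitespace-separated
  ``proteinA proteinB combined_score`` lines, an optional single header line,
  optionally gzip-compressed.  STRING lists every interaction in both
  orientations; the loader collapses the two records into one undirected edge
  and errors if the two orientations disagree on the score.
* Gene sets: one ID per line; blank lines and ``#`` comments ignored.
* Disease-class catalog: two-column TSV ``class_name<TAB>gene_id``.
* ID map: two-column TSV ``raw_id<TAB>network_id``.

All result tables are UTF-8 TSV with a header row and ``NA`` for missing.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import DataQualityWarning, ParseError, ValidationError
from .network import DiseaseClassCatalog, GeneSet, WeightedPPINetwork

__all__ = [
    "read_string_links",
    "read_gene_set",
    "read_class_catalog",
    "read_id_map",
    "map_and_filter",
    "write_string_links",
    "write_gene_set",
    "write_class_catalog",
    "write_per_gene_table",
    "write_class_summary",
    "write_pt_curves",
    "write_run_metadata",
]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _looks_like_header(fields: list[str]) -> bool:
    try:
        int(fields[-1])
    except ValueError:
        return True
    return False


def read_string_links(
    path: str | Path,
    min_score: int = 150,
    max_score: int = 999,
    *,
    validate_bounds: bool = True,
) -> WeightedPPINetwork:
    """Load a weighted PPI network from a ``protein.links``-style file.

    Symmetric duplicate lines (``a b s`` / ``b a s``) collapse to a single
    undirected edge; the number collapsed is stored on the returned network as
    ``duplicates_collapsed``.  With ``validate_bounds`` (default) any score
    outside ``[min_score, max_score]`` raises :class:`ValidationError`.
    """
    edges: dict[tuple[str, str], int] = {}
    n_dup = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and len(fields) >= 3 and _looks_like_header(fields):
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, raw_score = fields
            try:
                score = int(raw_score)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer score {raw_score!r}"
                ) from None
            if validate_bounds and not (min_score <= score <= max_score):
                raise ValidationError(
                    f"{path}: line {lineno}: score {score} outside "
                    f"[{min_score}, {max_score}]"
                )
            if a == b:
                raise ValidationError(f"{path}: line {lineno}: self-loop on {a!r}")
            key = (a, b) if a < b else (b, a)
            if key in edges:
                if edges[key] != score:
                    raise ValidationError(
                        f"{path}: line {lineno}: conflicting score for pair "
                        f"{key}: {edges[key]} vs {score}"
                    )
                n_dup += 1
            else:
                edges[key] = score
    net = WeightedPPINetwork.from_edges((a, b, s) for (a, b), s in edges.items())
    net.duplicates_collapsed = n_dup
    return net


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-ID-per-line gene list; duplicates are dropped with a warning."""
    ids: list[str] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line.split()[0])
    if not ids:
        raise ParseError(f"{path}: gene-set file contains no IDs")
    gene_set, n_dup = GeneSet.from_iterable(name, ids)
    if n_dup:
        warnings.warn(
            f"{path}: {n_dup} duplicate ID(s) dropped from gene set {name!r}",
            DataQualityWarning,
            stacklevel=2,
        )
    return gene_set


def read_class_catalog(path: str | Path, provenance: str = "") -> DiseaseClassCatalog:
    """Read a two-column ``class_name<TAB>gene_id`` catalog.

    Class order is first-seen order; a repeated (class, gene) row is kept once
    with a warning.  Genes may legitimately recur across classes.
    """
    memberships: dict[str, dict[str, None]] = {}
    n_dup = 0
    any_row = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}: line {lineno}: expected 'class<TAB>gene', got {line!r}"
                )
            any_row = True
            cls, gene = fields[0].strip(), fields[1].strip()
            members = memberships.setdefault(cls, {})
            if gene in members:
                n_dup += 1
            else:
                members[gene] = None
    if not any_row:
        raise ParseError(f"{path}: class catalog is empty")
    if n_dup:
        warnings.warn(
            f"{path}: {n_dup} duplicated (class, gene) row(s) kept once",
            DataQualityWarning,
            stacklevel=2,
        )
    catalog = DiseaseClassCatalog(provenance=provenance or str(path))
    for cls, members in memberships.items():
        catalog.add(GeneSet(cls, tuple(members)))
    return catalog


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping raw gene IDs to network protein IDs."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'raw<TAB>mapped', got {line!r}"
                )
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def map_and_filter(
    genes: GeneSet,
    mapping: Mapping[str, str] | None,
    network: WeightedPPINetwork,
) -> tuple[GeneSet, list[str]]:
    """Map raw IDs through an optional ID table and keep only network nodes.

    Returns the filtered set (first-occurrence order preserved) and the raw
    IDs dropped, in input order.  Two raw IDs mapping to the same network node
    collapse to one member with a warning.  The same function is applied to
    the query set and to every disease class.
    """
    kept: dict[str, str] = {}  # network-ID -> first raw ID
    dropped: list[str] = []
    n_collisions = 0
    for raw_id in genes.members:
        net_id = mapping.get(raw_id, raw_id) if mapping is not None else raw_id
        if net_id in network:
            if net_id in kept:
                n_collisions += 1
            else:
                kept[net_id] = raw_id
        else:
            dropped.append(raw_id)
    if n_collisions:
        warnings.warn(
            f"{n_collisions} raw ID(s) in {genes.name!r} collapsed onto an "
            "already-mapped network node",
            DataQualityWarning,
            stacklevel=2,
        )
    return GeneSet(genes.name, tuple(kept)), dropped


# -- writers ----------------------------------------------------------------


def write_string_links(
    network: WeightedPPINetwork, path: str | Path, *, header: bool = True
) -> None:
    """Write the network in the ``protein.links`` dialect (one line per edge)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("protein1 protein2 combined_score\n")
        for a, b, s in network.edges():
            fh.write(f"{a} {b} {s}\n")


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in gene_set:
            fh.write(gid + "\n")


def write_class_catalog(catalog: DiseaseClassCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene_set in catalog:
            for gid in gene_set:
                fh.write(f"{gene_set.name}\t{gid}\n")


def write_per_gene_table(results, path: str | Path) -> None:
    """Per-gene records for every class: gene_id, class, mis, lambda, p_value."""
    rows = [
        {
            "gene_id": rec.gene,
            "class": res.class_name,
            "mis": rec.mis,
            "lambda": rec.lambda_count,
            "p_value": rec.p_value,
        }
        for res in results
        for rec in res.records
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "class", "mis", "lambda", "p_value"])
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_class_summary(results, path: str | Path) -> None:
    rows = [
        {
            "class_name": res.class_name,
            "n_genes_input": res.n_genes_input,
            "n_genes_in_network": len(res.records),
            "auc": res.auc,
            "rank": res.rank,
        }
        for res in results
    ]
    df = pd.DataFrame(
        rows, columns=["class_name", "n_genes_input", "n_genes_in_network", "auc", "rank"]
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def write_pt_curves(results, path: str | Path) -> None:
    """Long-format PT-curve points: class, threshold, proportion."""
    rows = [
        {"class": res.class_name, "threshold": t, "proportion": p}
        for res in results
        for t, p in zip(res.curve.thresholds, res.curve.proportions)
    ]
    df = pd.DataFrame(rows, columns=["class", "threshold", "proportion"])
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_run_metadata(metadata: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
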