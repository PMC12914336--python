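"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices come in as TSV (header row = sample ids, first
column = gene ids), gene sets as GMT, interaction networks as two-column
edge lists, and run summaries go out as deterministic JSON.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, SampleGroups

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null", "none", "."}


def read_expression(path, collapse: str = "mean") -> ExpressionMatrix:
    """Read a genes x samples TSV, collapsing duplicate gene rows.

    Duplicate gene rows are collapsed by per-sample mean; rows still
    containing a missing value after collapse are dropped (drop count
    logged). Non-numeric cells and duplicate sample ids are rejected.
    """
    if collapse != "mean":
        raise ValueError(f"unsupported collapse rule {collapse!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = {s for s in header if header.count(s) > 1}
    if dup_cols:
        raise ValueError(f"{path}: duplicate sample ids {sorted(dup_cols)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() & ~raw.apply(
        lambda col: col.astype(str).str.strip().str.lower().isin(_MISSING_TOKENS)
    )
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iloc[r, c]!r}"
        )

    n_dup = int(numeric.index.duplicated().sum())
    collapsed = numeric.groupby(level=0, sort=False).mean()
    if n_dup:
        logger.info("%s: collapsed %d duplicate gene rows by mean", path, n_dup)

    has_missing = collapsed.isna().any(axis=1)
    n_drop = int(has_missing.sum())
    if n_drop:
        logger.info("%s: dropped %d gene rows with unresolved missing values", path, n_drop)
    kept = collapsed.loc[~has_missing]
    if kept.shape[0] == 0:
        raise ValueError(f"{path}: no gene rows left after missing-value filtering")
    return ExpressionMatrix.from_frame(kept)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_sample_groups(path, disease_name: str | None = None) -> SampleGroups:
    """Read a two-column TSV of sample_id -> case/control labels."""
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 fields, got {len(fields)}")
            sample, group = fields
            if ln == 1 and group.lower() in ("group", "label", "condition"):
                continue  # header row
            labels[sample] = group.lower()
    return SampleGroups(disease_name or path.stem, labels)


def write_sample_groups(groups: SampleGroups, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, label in groups.labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file (name, description, tab-separated members)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            unique: dict[str, None] = {}
            for m in members:
                unique.setdefault(m, None)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: deduplicated %d repeated members in set %r",
                    path, ln, len(members) - len(unique), name,
                )
            sets.append(GeneSet(name, tuple(unique), desc))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def read_edge_list(path) -> nx.Graph:
    """Read a two-column edge list into an undirected simple graph.

    Self-loops and duplicate edges are removed (counts logged); lines
    starting with ``#`` are comments.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 fields, got {len(fields)}")
            u, v = fields
            if u == v:
                n_self += 1
                continue
            if graph.has_edge(u, v):
                n_dup += 1
                continue
            graph.add_edge(u, v)
    if n_self or n_dup:
        logger.info("%s: removed %d self-loops and %d duplicate edges", path, n_self, n_dup)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# node_a\tnode_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(results: dict, path) -> None:
    """Write a run summary as deterministic (sorted-key) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
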