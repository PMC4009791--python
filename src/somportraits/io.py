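"""Readers and writers for the plain-text formats the package exchanges.

Formats
-------
expression TSV
    Header row of sample ids, first column gene ids, numeric body. UTF-8,
    tab-separated. Missing cells and duplicate ids are rejected on load.
GMT
    One gene set per line: ``name<TAB>category<TAB>member1<TAB>member2...``.
Newick
    Similarity trees with branch lengths; leaves keep input order.
weighted edge list
    ``idA<TAB>idB<TAB>r`` with each unordered pair written once.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, GeneSetCollection, SurvivalTable

_FLOAT_FMT = "%.12g"  # round trips are lossless at 12 significant digits


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | os.PathLike, scale: str = "raw") -> ExpressionMatrix:
    """Load a genes × samples TSV into an :class:`ExpressionMatrix`.

    Raises
    ------
    ValueError
        on ragged rows, non-numeric or missing cells, or duplicated ids. The
        error message names the offending id or row/column coordinate; no
        silent imputation is attempted.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n_cols = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}: ragged row at line {lineno}: expected {n_cols} "
                    f"fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row = []
            for j, cell in enumerate(fields[1:]):
                if cell == "" or cell.lower() in ("na", "nan"):
                    raise ValueError(
                        f"{path}: missing value at line {lineno} (gene "
                        f"{fields[0]!r}), column {sample_ids[j]!r}"
                    )
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                        f"column {sample_ids[j]!r}"
                    ) from None
            rows.append(row)
    data = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(data, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id",
                       float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; a GMT "
                    "line needs a name, a category and at least one member"
                )
            name, category, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m != ""]
            if not members:
                raise ValueError(f"{path}: gene set {name!r} (line {lineno}) has no members")
            collection.add(GeneSet(name=name, category=category, genes=tuple(members)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.category, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def read_survival_tsv(path: str | os.PathLike) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SurvivalTable(df)


def write_survival_tsv(table: SurvivalTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# trees and graphs
# ---------------------------------------------------------------------------

def write_newick(tree) -> str:
    """Serialize a ``skbio.TreeNode`` to a Newick string with branch lengths.

    Children keep their input order so the output is deterministic.
    """
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def write_edge_list(graph, path: str | os.PathLike, weight: str = "weight") -> None:
    """Write a weighted undirected graph as ``idA<TAB>idB<TAB>r`` lines.

    Each unordered pair appears once, in sorted node order. Self-edges are an
    error: a sample is trivially correlated with itself.
    """
    for u, v in graph.edges():
        if u == v:
            raise ValueError(f"self-edge on node {u!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            a, b = sorted((str(u), str(v)))
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT % data.get(weight, 1.0)}\n")
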