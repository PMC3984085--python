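"""Readers and writers: expression TSV, DREAM-style edge lists, SIF.

Expression matrices are plain tab-separated text with a header row of
sample identifiers and a label column of gene identifiers ('.' decimal
separator, UTF-8, LF).  Gold standards follow the DREAM convention:
``geneA<TAB>geneB<TAB>{0|1}`` with 1 marking a true interaction; pairs
absent from the file are negatives.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import CminetError, Dag, ExpressionMatrix, Skeleton, _norm_edge

_EDGELIST_HEADER = ["source", "target", "label", "kind"]


def read_expression(path: str | Path,
                    orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Parse a labeled numeric TSV into an :class:`ExpressionMatrix`.

    ``orientation="samples_in_rows"`` transposes after reading.  Malformed
    input (ragged rows, non-numeric cells, duplicate identifiers) raises
    with the offending line number.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise CminetError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CminetError(f"{path}: empty file") from None
        col_labels = header[1:]
        if not col_labels:
            raise CminetError(f"{path}: header has no sample columns")
        row_labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise CminetError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(rec)}")
            row_labels.append(rec[0])
            parsed = []
            for j, cell in enumerate(rec[1:], start=2):
                try:
                    v = float(cell)
                except ValueError:
                    raise CminetError(
                        f"{path}:{lineno}: non-numeric value {cell!r} "
                        f"in column {j} ({col_labels[j - 2]!r})") from None
                if not np.isfinite(v):
                    raise CminetError(
                        f"{path}:{lineno}: non-finite value {cell!r} in column {j}")
                parsed.append(v)
            rows.append(parsed)
    if len(set(row_labels)) != len(row_labels):
        dupe = next(g for g in row_labels if row_labels.count(g) > 1)
        raise CminetError(f"{path}: duplicate row identifier {dupe!r}")
    values = np.array(rows, dtype=float)
    if orientation == "samples_in_rows":
        return ExpressionMatrix(col_labels, row_labels, values.T)
    return ExpressionMatrix(row_labels, col_labels, values)


def write_expression(data: ExpressionMatrix, path: str | Path) -> None:
    """Write genes-in-rows TSV with 6 significant digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(data.samples) + "\n")
        for g, row in zip(data.genes, data.values):
            fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gold_standard(path: str | Path, vertices: Sequence[str]) -> Skeleton:
    """Parse a DREAM gold-standard edge list into a skeleton.

    Rows labeled 1 become undirected edges; both orientations of the same
    pair may appear with a consistent label, conflicting labels are an
    error, and unknown gene identifiers are rejected.
    """
    path = Path(path)
    vset = set(vertices)
    labels: dict[tuple[str, str], int] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:3] == _EDGELIST_HEADER[:3]:
                continue  # optional header written by write_network
            if len(fields) < 3:
                raise CminetError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, lab = fields[0], fields[1], fields[2]
            if lab not in ("0", "1"):
                raise CminetError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if a not in vset or b not in vset:
                raise CminetError(f"{path}:{lineno}: unknown gene in pair ({a!r}, {b!r})")
            if a == b:
                raise CminetError(f"{path}:{lineno}: self-loop on {a!r}")
            key = _norm_edge(a, b)
            val = int(lab)
            if key in labels and labels[key] != val:
                raise CminetError(f"{path}:{lineno}: conflicting labels for pair {key}")
            labels[key] = val
    edges = {e for e, v in labels.items() if v == 1}
    return Skeleton(list(vertices), edges)


def write_network(graph: Dag | Skeleton, path: str | Path,
                  fmt: str = "edgelist") -> None:
    """Write a graph deterministically (lexicographic edge order).

    ``edgelist`` emits ``source target label kind`` rows (kind flags
    directed vs undirected); ``sif`` uses the Cytoscape relation column
    (``regulates`` for directed, ``interacts`` for undirected).
    """
    path = Path(path)
    directed = isinstance(graph, Dag)
    edges = sorted(graph.directed_edges) if directed else sorted(graph.edges)
    kind = "directed" if directed else "undirected"
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if fmt == "edgelist":
            fh.write("\t".join(_EDGELIST_HEADER) + "\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\t1\t{kind}\n")
        elif fmt == "sif":
            rel = "regulates" if directed else "interacts"
            for a, b in edges:
                fh.write(f"{a}\t{rel}\t{b}\n")
        else:
            raise CminetError(f"unknown format {fmt!r}")
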