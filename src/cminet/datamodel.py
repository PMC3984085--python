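"""Core domain types shared across the inference pipeline.

The package works with four graph/data containers:

* :class:`ExpressionMatrix` — continuous gene × sample expression values;
* :class:`DiscretizedMatrix` — integer-level version of the above, used only
  by the MIT score;
* :class:`Skeleton` — an undirected graph over genes (the object the
  constraint-based pruning operates on);
* :class:`Dag` — a directed acyclic graph over genes with parent-set access
  (the object the score-and-search orientation operates on).

A :class:`CovarianceModel` caches the sample covariance matrix once per data
set so that all Gaussian (conditional) mutual-information evaluations reduce
to determinant ratios of its submatrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np


class CminetError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """Continuous expression data: genes in rows, samples in columns."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CminetError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise CminetError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise CminetError("gene identifiers must be unique")
        if len(self.genes) < 2:
            raise CminetError("need at least 2 genes")
        if not np.all(np.isfinite(self.values)):
            raise CminetError("expression values must be finite (no missing entries)")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise CminetError(f"unknown gene {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]


@dataclass
class DiscretizedMatrix:
    """Integer-level expression data plus per-gene level cardinalities.

    ``levels`` holds values in ``[1, cardinality[gene]]``; ``cardinality`` is
    the nominal number of bins requested at discretization time.  Scoring
    code uses the *observed* number of distinct levels instead, so empty bins
    never inflate chi-square penalties.
    """

    genes: list[str]
    samples: list[str]
    levels: np.ndarray
    cardinality: dict[str, int]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.shape != (len(self.genes), len(self.samples)):
            raise CminetError("levels shape does not match gene/sample labels")
        for i, g in enumerate(self.genes):
            lam = self.cardinality[g]
            row = self.levels[i]
            if row.min() < 1 or row.max() > lam:
                raise CminetError(f"levels of gene {g!r} fall outside [1, {lam}]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise CminetError(f"unknown gene {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.levels[self.gene_index(gene)]

    def observed_cardinality(self, gene: str) -> int:
        return int(np.unique(self.row(gene)).size)


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class Skeleton:
    """Undirected graph over genes: an unordered edge set, no self-loops."""

    vertices: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise CminetError(f"self-loop on {a!r}")
            if a not in vset or b not in vset:
                raise CminetError(f"edge ({a!r}, {b!r}) uses unknown vertex")
            norm.add(_norm_edge(a, b))
        self.edges = norm

    @classmethod
    def complete(cls, vertices: Sequence[str]) -> "Skeleton":
        vs = list(vertices)
        edges = {_norm_edge(a, b) for i, a in enumerate(vs) for b in vs[i + 1:]}
        return cls(vs, edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _norm_edge(a, b) in self.edges

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise CminetError(f"self-loop on {a!r}")
        self.edges.add(_norm_edge(a, b))

    def remove_edge(self, a: str, b: str) -> None:
        self.edges.discard(_norm_edge(a, b))

    def neighbors(self, v: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def copy(self) -> "Skeleton":
        return Skeleton(list(self.vertices), set(self.edges))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Skeleton):
            return NotImplemented
        return set(self.vertices) == set(other.vertices) and self.edges == other.edges

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.edges))


class Dag:
    """Directed acyclic graph over genes with parent-set access.

    Acyclicity is enforced on every mutation: :meth:`add_edge` rejects an
    edge that would close a directed cycle.
    """

    def __init__(self, vertices: Sequence[str],
                 directed_edges: Iterable[tuple[str, str]] = ()) -> None:
        self.vertices: list[str] = list(vertices)
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise CminetError("duplicate vertices")
        self._parents: dict[str, set[str]] = {v: set() for v in self.vertices}
        self._children: dict[str, set[str]] = {v: set() for v in self.vertices}
        for a, b in directed_edges:
            if a not in vset or b not in vset:
                raise CminetError(f"edge ({a!r}, {b!r}) uses unknown vertex")
            self.add_edge(a, b)

    # -- queries -----------------------------------------------------------
    @property
    def directed_edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self._parents.items() for p in ps}

    def parents(self, v: str) -> set[str]:
        return set(self._parents[v])

    def children(self, v: str) -> set[str]:
        return set(self._children[v])

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._children.get(a, ())

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self._parents.values())

    def reachable(self, src: str, dst: str) -> bool:
        """True when a directed path src -> ... -> dst exists."""
        stack, seen = [src], {src}
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            for c in self._children[v]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    # -- mutation ----------------------------------------------------------
    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise CminetError(f"self-loop on {a!r}")
        if self.has_edge(a, b):
            raise CminetError(f"edge {a!r}->{b!r} already present")
        if self.reachable(b, a):
            raise CminetError(f"edge {a!r}->{b!r} would create a cycle")
        self._children[a].add(b)
        self._parents[b].add(a)

    def remove_edge(self, a: str, b: str) -> None:
        if not self.has_edge(a, b):
            raise CminetError(f"edge {a!r}->{b!r} not present")
        self._children[a].discard(b)
        self._parents[b].discard(a)

    def would_be_acyclic_after_reversal(self, a: str, b: str) -> bool:
        """Check whether reversing a->b keeps the graph acyclic.

        Reversal creates a cycle iff a second directed path a ~> b exists
        besides the edge itself.
        """
        self.remove_edge(a, b)
        ok = not self.reachable(a, b)
        self.add_edge(a, b)
        return ok

    # -- derived views -----------------------------------------------------
    def skeleton(self) -> Skeleton:
        return Skeleton(list(self.vertices),
                        {_norm_edge(a, b) for a, b in self.directed_edges})

    def copy(self) -> "Dag":
        return Dag(self.vertices, self.directed_edges)

    def topological_order(self) -> list[str]:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.directed_edges)
        return list(nx.topological_sort(g))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return (set(self.vertices) == set(other.vertices)
                and self.directed_edges == other.directed_edges)

    def __repr__(self) -> str:
        return f"Dag({len(self.vertices)} vertices, {self.n_edges} edges)"


@dataclass
class CovarianceModel:
    """Sample covariance matrix of an expression data set."""

    genes: list[str]
    cov: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        self._index = {g: i for i, g in enumerate(self.genes)}

    def indices(self, genes: Iterable[str]) -> list[int]:
        try:
            return [self._index[g] for g in genes]
        except KeyError as exc:
            raise CminetError(f"unknown gene {exc.args[0]!r}") from None

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        idx = self.indices(genes)
        return self.cov[np.ix_(idx, idx)]

    def variance(self, gene: str) -> float:
        i = self.indices([gene])[0]
        return float(self.cov[i, i])


def covariance_model(data: ExpressionMatrix) -> CovarianceModel:
    """Sample covariance (n-1 denominator) of all gene pairs.

    MI/CMI are ratio-of-determinant quantities, so the normalization
    constant cancels; the unbiased convention is fixed for reproducibility.
    """
    if data.n_samples < 2:
        raise CminetError("insufficient samples: covariance needs at least 2")
    cov = np.cov(data.values, ddof=1)
    cov = np.atleast_2d(cov)
    for i, g in enumerate(data.genes):
        if cov[i, i] <= 0.0:
            warnings.warn(f"gene {g!r} has zero variance; "
                          "downstream independence tests will reject it")
    return CovarianceModel(list(data.genes), cov, data.n_samples)
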