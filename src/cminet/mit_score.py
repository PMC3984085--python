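"""The MIT (mutual information test) score for discrete Bayesian networks.

The score of a DAG decomposes into per-node local terms

    g(X_i, Pa_i) = 2 N * MI_D(X_i; Pa_i) - sum_j chi2_quantile(alpha, l_j)

where ``MI_D`` is the empirical mutual information between the node and the
joint configuration of its parents, N is the number of measurements, and
the ``l_j`` are degrees of freedom accumulated parent by parent:

    l_j = (r_i - 1) (r_sigma(j) - 1) * prod_{k<j} r_sigma(k)

with the parents taken in decreasing order of level cardinality (ties by
gene order in the data).  Cardinalities ``r`` count *observed* distinct
levels, so empty bins never inflate the penalty.  A node with no parents
scores 0.

The score is decomposable but not score-equivalent: reversing an edge can
change the total, which is exactly what makes it usable for orienting a
skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import chi2

from .datamodel import CminetError, Dag, DiscretizedMatrix


@dataclass
class LocalScore:
    node: str
    parents: frozenset[str]
    value: float
    mi_term: float
    penalty_term: float


def _parent_codes(parents: list[str], ddata: DiscretizedMatrix) -> np.ndarray:
    """Encode each sample's joint parent configuration as a single integer."""
    rows = np.stack([ddata.row(p) for p in parents])
    _, codes = np.unique(rows.T, axis=0, return_inverse=True)
    return codes


def empirical_mi(node: str, parents: Iterable[str],
                 ddata: DiscretizedMatrix) -> float:
    """Empirical MI (nats) between a node and its joint parent configuration.

    Computed from the contingency table of node levels against parent
    configurations, with the 0*ln(0) = 0 convention.
    """
    ps = sorted(parents)
    if not ps:
        return 0.0
    n = ddata.n_samples
    node_lv = ddata.row(node)
    codes = _parent_codes(ps, ddata)
    cells, counts = np.unique(np.stack([node_lv, codes], axis=1), axis=0,
                              return_counts=True)
    n_i = np.bincount(node_lv)[cells[:, 0]]
    n_k = np.bincount(codes)[cells[:, 1]]
    total = float(np.sum(counts * np.log(n * counts / (n_i * n_k))))
    return max(total / n, 0.0)


def dof_sequence(node: str, parents: Iterable[str],
                 ddata: DiscretizedMatrix) -> list[int]:
    """Degrees of freedom per parent, in canonical (decreasing-cardinality) order."""
    ps = list(parents)
    if not ps:
        return []
    r_node = ddata.observed_cardinality(node)
    gene_pos = {g: i for i, g in enumerate(ddata.genes)}
    # canonical sigma*: decreasing cardinality, ties broken by data gene order
    ordered = sorted(ps, key=lambda g: (-ddata.observed_cardinality(g), gene_pos[g]))
    dofs = []
    prefix = 1
    for g in ordered:
        r = ddata.observed_cardinality(g)
        dofs.append((r_node - 1) * (r - 1) * prefix)
        prefix *= r
    return dofs


def local_mit(node: str, parents: Iterable[str], ddata: DiscretizedMatrix,
              alpha_score: float) -> LocalScore:
    """Local MIT score of one node given its parent set."""
    if not 0.0 < alpha_score < 1.0:
        raise CminetError("alpha_score must lie in (0, 1)")
    ps = frozenset(parents)
    if not ps:
        return LocalScore(node, ps, 0.0, 0.0, 0.0)
    n = ddata.n_samples
    mi_term = 2.0 * n * empirical_mi(node, ps, ddata)
    dofs = dof_sequence(node, ps, ddata)
    penalty = float(sum(chi2.ppf(alpha_score, l) for l in dofs if l > 0))
    return LocalScore(node, ps, mi_term - penalty, mi_term, penalty)


class ScoreCache:
    """Memoizes local scores keyed by (node, frozen parent set)."""

    def __init__(self, ddata: DiscretizedMatrix, alpha_score: float) -> None:
        self.ddata = ddata
        self.alpha_score = alpha_score
        self._store: dict[tuple[str, frozenset[str]], LocalScore] = {}
        self.hits = 0
        self.misses = 0

    def local(self, node: str, parents: Iterable[str]) -> LocalScore:
        key = (node, frozenset(parents))
        found = self._store.get(key)
        if found is not None:
            self.hits += 1
            return found
        self.misses += 1
        score = local_mit(node, key[1], self.ddata, self.alpha_score)
        self._store[key] = score
        return score


def total_mit(dag: Dag, ddata: DiscretizedMatrix, alpha_score: float,
              cache: ScoreCache | None = None) -> float:
    """Total MIT score: the sum of local scores over all nodes."""
    if cache is None:
        cache = ScoreCache(ddata, alpha_score)
    return sum(cache.local(v, dag.parents(v)).value for v in dag.vertices)


def delta_move(dag: Dag, move: str, x: str, y: str, ddata: DiscretizedMatrix,
               alpha_score: float, cache: ScoreCache | None = None) -> float:
    """Score change of applying a local move, touching only affected nodes.

    ``add``/``delete`` re-score only y; ``reverse`` (x->y becomes y->x)
    re-scores x and y.  The caller is responsible for acyclicity.
    """
    if cache is None:
        cache = ScoreCache(ddata, alpha_score)
    pa_y = dag.parents(y)
    if move == "add":
        if dag.has_edge(x, y):
            raise CminetError(f"cannot add existing edge {x!r}->{y!r}")
        return (cache.local(y, pa_y | {x}).value - cache.local(y, pa_y).value)
    if move == "delete":
        if not dag.has_edge(x, y):
            raise CminetError(f"cannot delete absent edge {x!r}->{y!r}")
        return (cache.local(y, pa_y - {x}).value - cache.local(y, pa_y).value)
    if move == "reverse":
        if not dag.has_edge(x, y):
            raise CminetError(f"cannot reverse absent edge {x!r}->{y!r}")
        pa_x = dag.parents(x)
        return (cache.local(y, pa_y - {x}).value - cache.local(y, pa_y).value
                + cache.local(x, pa_x | {y}).value - cache.local(x, pa_x).value)
    raise CminetError(f"unknown move {move!r}")
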