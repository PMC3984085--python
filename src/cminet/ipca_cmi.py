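"""IPCA-CMI: CMI pruning with weight-selected conditioning sets, interleaved
with MIT-scored hill-climbing orientation.

The hybrid pipeline alternates a constraint step with a score step:

* order 0 — prune the complete graph by marginal MI, then orient the
  surviving skeleton by reversal-only hill climbing on the MIT score
  (50 random restarts), giving the DAG D_0;
* order i >= 1 — for each remaining edge (X, Y), candidate separators are
  *all* genes adjacent to X or to Y in D_{i-1} (a superset of the common
  neighbours PCA-CMI uses).  Each candidate Z receives a weight w(Z): the
  number of short undirected simple paths starting at X or at Y on which Z
  sits as a chain or fork node — i.e. paths that conditioning on Z would
  block.  Candidates whose weight reaches the median weight k form the
  selected set K; the edge is removed when the maximum CMI over all
  i-subsets of K falls below theta.  After the sweep the pruned skeleton is
  re-oriented, giving D_i.

The loop stops at the first order where no edge has a selected set of at
least i candidates.  CMI is always evaluated on the continuous data;
discretization feeds only the MIT score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .datamodel import (CminetError, CovarianceModel, Dag, ExpressionMatrix,
                        Skeleton, covariance_model)
from .discretize import discretize
from .evaluation import ConfusionMetrics, confusion
from .infotheory import conditional_mutual_information
from .mit_score import ScoreCache
from .pca_cmi import prune_order0
from .search import SearchConfig, restarted_search

log = logging.getLogger(__name__)


@dataclass
class WeightTable:
    """Blocked-path weights of the separator candidates for one edge."""

    center_pair: tuple[str, str]
    weights: dict[str, int]
    k: float
    selected: set[str]


def blocked_path_weight(z: str, x: str, y: str, dag: Dag,
                        length_cap: int | None = 4) -> int:
    """Count short undirected simple paths from x or y that z would block.

    A path (no repeated vertices, at most ``length_cap`` edges, unlimited
    when the cap is None) starting at x or at y is credited to z when z
    appears on it as an interior chain or fork node — the configurations
    that conditioning on {z} blocks.  Collider occurrences of z are not
    credited: conditioning on a collider opens rather than blocks.
    """
    skel = dag.skeleton()
    if z in (x, y):
        raise CminetError("z must differ from x and y")
    if z not in skel.neighbors(x) and z not in skel.neighbors(y):
        raise CminetError(f"{z!r} is adjacent to neither {x!r} nor {y!r}")
    adj = {v: sorted(skel.neighbors(v)) for v in skel.vertices}

    def count_from(start: str) -> int:
        total = 0
        # stack holds (path, visited); paths are undirected vertex sequences
        stack = [([start], {start})]
        while stack:
            path, visited = stack.pop()
            if len(path) >= 3 and z in path[1:-1]:
                pos = path.index(z)
                before, after = path[pos - 1], path[pos + 1]
                collider = dag.has_edge(before, z) and dag.has_edge(after, z)
                if not collider:
                    total += 1
            if length_cap is not None and len(path) - 1 >= length_cap:
                continue
            for nxt in adj[path[-1]]:
                if nxt not in visited:
                    stack.append((path + [nxt], visited | {nxt}))
        return total

    return count_from(x) + count_from(y)


def selected_set(x: str, y: str, dag: Dag,
                 length_cap: int | None = 4) -> WeightTable:
    """Weight every gene adjacent to x or y and keep those at or above the
    median weight k (even candidate count: mean of the two middle values)."""
    skel = dag.skeleton()
    candidates = sorted((skel.neighbors(x) | skel.neighbors(y)) - {x, y})
    if not candidates:
        return WeightTable((x, y), {}, 0.0, set())
    weights = {z: blocked_path_weight(z, x, y, dag, length_cap)
               for z in candidates}
    k = float(np.median(list(weights.values())))
    selected = {z for z, w in weights.items() if w >= k}
    return WeightTable((x, y), weights, k, selected)


def run_ipca_cmi(data: ExpressionMatrix, theta: float,
                 alpha_score: float = 0.999,
                 config: SearchConfig | None = None,
                 lam: int = 10, disc_method: str = "ewd",
                 length_cap: int | None = 4,
                 max_order: int | None = None) -> tuple[Dag, int]:
    """Run the full hybrid pipeline; returns the final DAG and the highest
    order at which any conditional test was performed."""
    if theta < 0:
        raise CminetError("theta must be nonnegative")
    if config is None:
        config = SearchConfig(move_set="orient_only")
    config = replace(config, move_set="orient_only")
    model = covariance_model(data)
    ddata = discretize(data, lam, disc_method)
    cache = ScoreCache(ddata, alpha_score)
    genes = list(data.genes)

    skeleton = Skeleton.complete(genes)
    prune_order0(skeleton, model, theta, genes)
    dag, score = restarted_search(skeleton, ddata, alpha_score, config, cache)
    log.info("order 0: %d edges, HC score %.4f", skeleton.n_edges, score)
    order_reached = 0
    if max_order is not None and max_order <= 0:
        return dag, order_reached

    order = 1
    while True:
        prev_dag = dag
        skeleton = prev_dag.skeleton()
        any_testable = False
        changed = False
        for i, x in enumerate(genes):
            for y in genes[i + 1:]:
                if not skeleton.has_edge(x, y):
                    continue
                table = selected_set(x, y, prev_dag, length_cap)
                pool = sorted(table.selected, key=genes.index)
                if len(pool) < order:
                    continue
                any_testable = True
                best = -1.0
                try:
                    for sub in combinations(pool, order):
                        best = max(best, conditional_mutual_information(
                            x, y, sub, model))
                except CminetError as exc:
                    warnings.warn(f"keeping edge ({x}, {y}): {exc}")
                    continue
                if best < theta:
                    skeleton.remove_edge(x, y)
                    changed = True
        if not any_testable:
            break
        order_reached = order
        if changed:
            orient_cfg = replace(config, seed=int(config.seed) + 1009 * order)
            dag, score = restarted_search(skeleton, ddata, alpha_score,
                                          orient_cfg, cache)
        log.info("order %d: %d edges, HC score %.4f",
                 order, skeleton.n_edges, score)
        if max_order is not None and order >= max_order:
            break
        order += 1
    return dag, order_reached


def repeated_runs(data: ExpressionMatrix, truth: Skeleton, theta: float,
                  alpha_score: float = 0.999,
                  config: SearchConfig | None = None,
                  lam: int = 10, disc_method: str = "ewd",
                  n_runs: int = 100,
                  length_cap: int | None = 4) -> ConfusionMetrics:
    """Average skeleton confusion metrics over repeated randomized runs.

    The search restarts make the pipeline stochastic, so the headline
    numbers are means over ``n_runs`` runs seeded seed+1 .. seed+n_runs;
    counts and every derived metric are averaged arithmetically.
    """
    if n_runs < 1:
        raise CminetError("n_runs must be >= 1")
    if config is None:
        config = SearchConfig(move_set="orient_only")
    results = []
    for r in range(1, n_runs + 1):
        cfg = replace(config, seed=int(config.seed) + r)
        dag, _ = run_ipca_cmi(data, theta, alpha_score, cfg, lam, disc_method,
                              length_cap)
        results.append(confusion(dag.skeleton(), truth))
    fields = ("tp", "fp", "tn", "fn", "acc", "fpr", "fdr", "ppv", "f",
              "mcc", "tpr")
    means = {f: float(np.mean([getattr(m, f) for m in results]))
             for f in fields}
    return ConfusionMetrics(**means)
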