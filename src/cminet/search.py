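"""Hill-climbing maximization of the MIT score with random restarts.

Two move regimes are supported:

* ``full`` — add / delete / reverse an edge, the classical DAG-space
  neighbourhood;
* ``orient_only`` — only reversals of existing edges, which keeps the
  skeleton fixed and is used to orient a constraint-learned skeleton.

Each climb greedily applies the best strictly improving legal move (ties
broken lexicographically by (move-type, x, y)) and stops at a local
optimum.  Restarts draw fresh random initial DAGs (or random acyclic
orientations of the skeleton) and the best-scoring result wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CminetError, Dag, DiscretizedMatrix, Skeleton
from .mit_score import ScoreCache, delta_move, total_mit


@dataclass
class SearchConfig:
    restarts: int = 50
    max_iterations: int | None = None  # default 10 * n^2, set per climb
    seed: int = 0
    move_set: str = "full"  # "full" | "orient_only"
    max_parents: int = 3

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise CminetError("restarts must be >= 1")
        if self.move_set not in ("full", "orient_only"):
            raise CminetError(f"unknown move set {self.move_set!r}")


def random_dag(vertices: list[str], seed: int, max_parents: int) -> Dag:
    """Uniformly ordered random DAG: random topological order, then random
    parents drawn from each node's predecessors."""
    if max_parents < 0:
        raise CminetError("max_parents must be >= 0")
    rng = np.random.default_rng(seed)
    order = [vertices[i] for i in rng.permutation(len(vertices))]
    dag = Dag(vertices)
    for pos, v in enumerate(order):
        cap = min(max_parents, pos)
        if cap == 0:
            continue
        k = int(rng.integers(0, cap + 1))
        if k:
            for p in rng.choice(pos, size=k, replace=False):
                dag.add_edge(order[int(p)], v)
    return dag


def random_orientation(skeleton: Skeleton, seed: int) -> Dag:
    """Orient every skeleton edge along a random vertex permutation.

    Orienting along a total order cannot create a cycle, so the result is
    acyclic by construction and preserves the skeleton exactly.
    """
    rng = np.random.default_rng(seed)
    vs = list(skeleton.vertices)
    rank = {vs[i]: r for r, i in enumerate(rng.permutation(len(vs)))}
    dag = Dag(vs)
    for a, b in sorted(skeleton.edges):
        if rank[a] < rank[b]:
            dag.add_edge(a, b)
        else:
            dag.add_edge(b, a)
    return dag


_MOVE_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def _legal_moves(dag: Dag, move_set: str):
    vs = sorted(dag.vertices)
    if move_set == "orient_only":
        for x, y in sorted(dag.directed_edges):
            if dag.would_be_acyclic_after_reversal(x, y):
                yield ("reverse", x, y)
        return
    for x in vs:
        for y in vs:
            if x == y:
                continue
            if dag.has_edge(x, y):
                yield ("delete", x, y)
                if dag.would_be_acyclic_after_reversal(x, y):
                    yield ("reverse", x, y)
            elif not dag.has_edge(y, x) and not dag.reachable(y, x):
                yield ("add", x, y)


def _apply(dag: Dag, move: str, x: str, y: str) -> None:
    if move == "add":
        dag.add_edge(x, y)
    elif move == "delete":
        dag.remove_edge(x, y)
    elif move == "reverse":
        dag.remove_edge(x, y)
        dag.add_edge(y, x)
    else:  # pragma: no cover
        raise CminetError(f"unknown move {move!r}")


def hill_climb(initial: Dag, ddata: DiscretizedMatrix, alpha_score: float,
               config: SearchConfig,
               cache: ScoreCache | None = None) -> tuple[Dag, float]:
    """Greedy ascent from ``initial``; returns the local optimum and its score.

    Only strictly improving moves are accepted; among equal best deltas the
    lexicographically smallest (move-type, x, y) wins, making the trajectory
    deterministic for a given start.
    """
    if cache is None:
        cache = ScoreCache(ddata, alpha_score)
    dag = initial.copy()
    score = total_mit(dag, ddata, alpha_score, cache)
    n = len(dag.vertices)
    cap = config.max_iterations if config.max_iterations else 10 * n * n
    for _ in range(cap):
        best = None
        best_delta = 0.0
        for move, x, y in _legal_moves(dag, config.move_set):
            d = delta_move(dag, move, x, y, ddata, alpha_score, cache)
            key = (_MOVE_ORDER[move], x, y)
            if d > best_delta + 1e-12 or (
                    best is not None and abs(d - best_delta) <= 1e-12 and key < best):
                best = key
                best_delta = d
        if best is None:
            break
        move = ("add", "delete", "reverse")[best[0]]
        _apply(dag, move, best[1], best[2])
        score += best_delta
    return dag, score


def restarted_search(skeleton: Skeleton | None, ddata: DiscretizedMatrix,
                     alpha_score: float, config: SearchConfig,
                     cache: ScoreCache | None = None) -> tuple[Dag, float]:
    """Best of ``config.restarts`` independent climbs (seeds seed+i).

    ``orient_only`` requires a skeleton and starts from random acyclic
    orientations of it; ``full`` starts from random DAGs over the data's
    genes.
    """
    if cache is None:
        cache = ScoreCache(ddata, alpha_score)
    if config.move_set == "orient_only" and skeleton is None:
        raise CminetError("orient_only search needs a skeleton")
    best_dag: Dag | None = None
    best_score = -np.inf
    for i in range(config.restarts):
        seed_i = int(config.seed) + i
        if config.move_set == "orient_only":
            start = random_orientation(skeleton, seed_i)
        else:
            start = random_dag(list(ddata.genes), seed_i, config.max_parents)
        dag, score = hill_climb(start, ddata, alpha_score, config, cache)
        if score > best_score:
            best_dag, best_score = dag, score
    assert best_dag is not None
    return best_dag, float(best_score)
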