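"""Path-consistency skeleton learning with Gaussian CMI tests (PCA-CMI).

Starting from the complete undirected graph, edges are deleted order by
order: at order 0 an edge (X, Y) is removed when MI(X;Y) < theta; at order
i >= 1 the conditioning candidates are the *common* neighbours of X and Y,
every i-subset is tried, and the edge is removed when the maximum CMI over
those subsets falls below theta.  Deletions take effect immediately within
an order, following the sequential gene-pair loop.  The algorithm stops at
the first order where no edge has enough common neighbours to test.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

from .datamodel import CminetError, CovarianceModel, ExpressionMatrix, Skeleton, covariance_model
from .infotheory import conditional_mutual_information, mutual_information

log = logging.getLogger(__name__)


def _max_cmi(x: str, y: str, candidates: list[str], order: int,
             model: CovarianceModel) -> float:
    """Maximum CMI(X;Y|H) over all order-sized subsets H of the candidates."""
    best = -1.0
    for sub in combinations(candidates, order):
        best = max(best, conditional_mutual_information(x, y, sub, model))
    return best


def prune_order0(skeleton: Skeleton, model: CovarianceModel, theta: float,
                 gene_order: list[str]) -> None:
    """Remove every edge whose marginal MI falls below theta (in place)."""
    for i, x in enumerate(gene_order):
        for y in gene_order[i + 1:]:
            if not skeleton.has_edge(x, y):
                continue
            try:
                mi = mutual_information(x, y, model)
            except CminetError as exc:
                warnings.warn(f"keeping edge ({x}, {y}): {exc}")
                continue
            if mi < theta:
                skeleton.remove_edge(x, y)


def run_pca_cmi(data: ExpressionMatrix, theta: float,
                max_order: int | None = None) -> tuple[Skeleton, int]:
    """Learn a skeleton by order-increasing CMI-based edge deletion.

    Returns the final skeleton and the highest order at which any
    conditional test was actually performed (0 when only marginal MI tests
    ran).
    """
    if theta < 0:
        raise CminetError("theta must be nonnegative")
    model = covariance_model(data)
    genes = list(data.genes)
    skeleton = Skeleton.complete(genes)
    prune_order0(skeleton, model, theta, genes)
    order_reached = 0
    if max_order is not None and max_order <= 0:
        return skeleton, order_reached
    order = 1
    while True:
        any_testable = False
        for i, x in enumerate(genes):
            for y in genes[i + 1:]:
                if not skeleton.has_edge(x, y):
                    continue
                common = sorted((skeleton.neighbors(x) & skeleton.neighbors(y))
                                - {x, y}, key=genes.index)
                if len(common) < order:
                    continue
                any_testable = True
                try:
                    stat = _max_cmi(x, y, common, order, model)
                except CminetError as exc:
                    warnings.warn(f"keeping edge ({x}, {y}): {exc}")
                    continue
                if stat < theta:
                    skeleton.remove_edge(x, y)
        if not any_testable:
            break
        order_reached = order
        log.info("order %d: %d edges remain", order, skeleton.n_edges)
        if max_order is not None and order >= max_order:
            break
        order += 1
    return skeleton, order_reached
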