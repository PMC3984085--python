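"""Skeleton evaluation: confusion counts, derived measures, and the
probability of drawing a predicted subgraph at random.

All evaluation is over unordered gene pairs: an edge is a positive, a
non-edge a negative, so TP+FP+TN+FN always equals n(n-1)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datamodel import CminetError, Skeleton


@dataclass
class ConfusionMetrics:
    """Confusion counts plus the eight standard derived measures.

    Counts may be fractional when they are averages over repeated runs.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    acc: float
    fpr: float
    fdr: float
    ppv: float
    f: float
    mcc: float
    tpr: float


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0")
        return 0.0
    return num / den


def metrics_from_counts(tp: float, fp: float, tn: float, fn: float) -> ConfusionMetrics:
    """Derive ACC/FPR/FDR/PPV/F/MCC/TPR from raw confusion counts."""
    total = tp + fp + tn + fn
    acc = _safe_div(tp + tn, total, "ACC")
    fpr = _safe_div(fp, fp + tn, "FPR")
    fdr = _safe_div(fp, fp + tp, "FDR")
    ppv = _safe_div(tp, tp + fp, "PPV")
    tpr = _safe_div(tp, tp + fn, "TPR")
    f = _safe_div(2 * ppv * tpr, ppv + tpr, "F")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, float(mcc_den), "MCC")
    return ConfusionMetrics(tp, fp, tn, fn, acc, fpr, fdr, ppv, f, mcc, tpr)


def confusion(predicted: Skeleton, truth: Skeleton) -> ConfusionMetrics:
    """Compare a predicted skeleton against a gold standard one."""
    if set(predicted.vertices) != set(truth.vertices):
        raise CminetError("predicted and truth skeletons have different vertices")
    n = len(truth.vertices)
    total = n * (n - 1) // 2
    tp = len(predicted.edges & truth.edges)
    fp = len(predicted.edges - truth.edges)
    fn = len(truth.edges - predicted.edges)
    tn = total - tp - fp - fn
    return metrics_from_counts(tp, fp, tn, fn)


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def subgraph_probability(n_genes: int, m_true: int, tp: int, fp: int) -> float:
    """Probability of drawing the predicted subgraph by chance.

    The hypergeometric point probability of picking exactly ``tp`` of the
    ``m_true`` true edges and ``fp`` of the remaining non-edges when
    selecting ``tp + fp`` of all n(n-1)/2 possible edges uniformly:

        C(m, tp) * C(P - m, fp) / C(P, tp + fp)

    Evaluated in log space so it stays finite for hundreds of genes.  The
    smaller the probability, the less likely the prediction arose by chance.
    """
    pairs = n_genes * (n_genes - 1) // 2
    if not 0 <= m_true <= pairs:
        raise CminetError("m_true must lie in [0, n(n-1)/2]")
    if not 0 <= tp <= m_true:
        raise CminetError("tp must lie in [0, m_true]")
    if not 0 <= fp <= pairs - m_true:
        raise CminetError("fp must lie in [0, pairs - m_true]")
    logp = (_log_comb(m_true, tp) + _log_comb(pairs - m_true, fp)
            - _log_comb(pairs, tp + fp))
    return float(np.exp(logp))
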