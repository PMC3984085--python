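"""Gaussian entropy, mutual information and conditional mutual information.

Under the Gaussian assumption for expression data the differential entropy
of a p-dimensional vector with covariance S is

    H = 1/2 * ln((2*pi*e)^p * |S|)

and MI / CMI reduce to log-ratios of covariance determinants:

    MI(X;Y)      = 1/2 * ln( var(X) var(Y) / |S_XY| )
    CMI(X;Y|Z)   = 1/2 * ln( |S_XZ| |S_YZ| / (|S_Z| |S_XYZ|) )

All quantities are in nats.  The (conditional) independence decision is a
direct threshold on the statistic by default; a Fisher-z p-value mode is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .datamodel import CminetError, CovarianceModel

#: determinants below this are treated as degenerate rather than mapped to +-inf
_DET_FLOOR = 1e-300

_LOG_2PIE = float(np.log(2.0 * np.pi * np.e))


@dataclass
class IndependenceDecision:
    """Outcome of one (conditional) independence test."""

    statistic: float
    order: int
    independent: bool
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.statistic < -1e-12:
            raise CminetError(f"negative information statistic {self.statistic}")


def _det(matrix: np.ndarray, what: str = "covariance") -> float:
    d = float(np.linalg.det(np.atleast_2d(matrix)))
    if d < _DET_FLOOR:
        raise CminetError(f"degenerate {what}: determinant {d} is not positive")
    return d


def gaussian_entropy(cov_submatrix: np.ndarray) -> float:
    """Entropy (nats) of a Gaussian vector with the given covariance."""
    s = np.atleast_2d(np.asarray(cov_submatrix, dtype=float))
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-8):
        raise CminetError("covariance submatrix must be square and symmetric")
    p = s.shape[0]
    return 0.5 * (p * _LOG_2PIE + np.log(_det(s)))


def mutual_information(x: str, y: str, model: CovarianceModel) -> float:
    """MI(X;Y) in nats from the covariance model."""
    if x == y:
        raise CminetError("mutual information of a gene with itself is undefined here")
    vx, vy = model.variance(x), model.variance(y)
    if vx <= 0 or vy <= 0:
        raise CminetError(f"degenerate gene: zero variance in ({x!r}, {y!r})")
    det_xy = _det(model.submatrix([x, y]))
    return 0.5 * float(np.log(vx * vy / det_xy))


def conditional_mutual_information(x: str, y: str, z_set: Iterable[str],
                                   model: CovarianceModel) -> float:
    """CMI(X;Y|Z) in nats; reduces to MI for an empty conditioning set."""
    z = list(z_set)
    if x in z or y in z:
        raise CminetError("conditioning set must not contain x or y")
    if x == y:
        raise CminetError("x and y must differ")
    if not z:
        return mutual_information(x, y, model)
    det_xz = _det(model.submatrix([x] + z))
    det_yz = _det(model.submatrix([y] + z))
    det_z = _det(model.submatrix(z))
    det_xyz = _det(model.submatrix([x, y] + z))
    return 0.5 * float(np.log(det_xz * det_yz / (det_z * det_xyz)))


def independence_test(x: str, y: str, z_set: Sequence[str],
                      model: CovarianceModel, theta: float = 0.05,
                      mode: str = "threshold",
                      alpha_test: float = 0.05) -> IndependenceDecision:
    """Decide conditional independence of x and y given z_set.

    ``threshold`` mode declares independence when CMI < theta.  ``pvalue``
    mode converts the statistic to a partial correlation, applies the
    Fisher z-transform with n - |Z| - 3 effective degrees of freedom and
    declares independence when the two-sided p-value >= alpha_test.
    """
    z = list(z_set)
    stat = conditional_mutual_information(x, y, z, model)
    stat = max(stat, 0.0)  # clip tiny negative round-off
    order = len(z)
    if mode == "threshold":
        if theta < 0:
            raise CminetError("theta must be nonnegative")
        return IndependenceDecision(stat, order, independent=stat < theta)
    if mode == "pvalue":
        if not 0.0 < alpha_test < 1.0:
            raise CminetError("alpha_test must lie in (0, 1)")
        dof = model.n_samples - order - 3
        if dof <= 0:
            raise CminetError("insufficient samples for order "
                              f"{order}: need n > {order + 3}")
        rho = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * stat))))
        rho = min(rho, 1.0 - 1e-15)
        zstat = 0.5 * np.log((1.0 + rho) / (1.0 - rho)) * np.sqrt(dof)
        p = float(2.0 * (1.0 - norm.cdf(zstat)))
        return IndependenceDecision(stat, order, independent=p >= alpha_test,
                                    p_value=p)
    raise CminetError(f"unknown test mode {mode!r}")
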