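"""Equal-width and equal-frequency discretization of expression data.

The MIT score operates on discrete variables, so continuous expression
values must be binned first.  Two standard unsupervised schemes are
provided, each applied per gene:

* equal width (EWD): the range [min, max] of a gene is cut into ``lam``
  intervals of equal width;
* equal frequency (EFD): the sorted values are split into ``lam`` groups
  whose sizes differ by at most one.

Bins are half-open ``[low, high)`` with the last bin closed, so a value
sitting exactly on a cut point belongs to the upper bin and the maximum
maps to level ``lam``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import CminetError, DiscretizedMatrix, ExpressionMatrix


def equal_width(data: ExpressionMatrix, lam: int) -> DiscretizedMatrix:
    """Bin each gene into ``lam`` equal-width intervals over its own range."""
    if lam < 2:
        raise CminetError("equal_width needs at least 2 bins")
    levels = np.empty_like(data.values, dtype=int)
    cardinality: dict[str, int] = {}
    for i, gene in enumerate(data.genes):
        row = data.values[i]
        lo, hi = float(row.min()), float(row.max())
        if hi == lo:
            warnings.warn(f"gene {gene!r} is constant; all samples in level 1")
            levels[i] = 1
            cardinality[gene] = 1
            continue
        width = (hi - lo) / lam
        lv = np.floor((row - lo) / width).astype(int) + 1
        levels[i] = np.clip(lv, 1, lam)
        cardinality[gene] = lam
    return DiscretizedMatrix(list(data.genes), list(data.samples), levels,
                             cardinality)


def equal_frequency(data: ExpressionMatrix, lam: int) -> DiscretizedMatrix:
    """Bin each gene into ``lam`` groups of near-equal occupancy.

    Group sizes differ by at most one (larger groups first); ties are
    resolved by a stable sort on (value, sample position), so equal values
    keep their column order.
    """
    if lam < 2:
        raise CminetError("equal_frequency needs at least 2 bins")
    if lam > data.n_samples:
        raise CminetError(f"cannot form {lam} groups from {data.n_samples} samples")
    m = data.n_samples
    base, extra = divmod(m, lam)
    group_sizes = [base + 1] * extra + [base] * (lam - extra)
    levels = np.empty_like(data.values, dtype=int)
    cardinality: dict[str, int] = {}
    for i, gene in enumerate(data.genes):
        row = data.values[i]
        order = np.argsort(row, kind="stable")
        lv = np.empty(m, dtype=int)
        pos = 0
        for level, size in enumerate(group_sizes, start=1):
            lv[order[pos:pos + size]] = level
            pos += size
        if row.min() == row.max():
            warnings.warn(f"gene {gene!r} is constant; all samples in level 1")
            lv[:] = 1
            cardinality[gene] = 1
        else:
            cardinality[gene] = lam
        levels[i] = lv
    return DiscretizedMatrix(list(data.genes), list(data.samples), levels,
                             cardinality)


_METHODS = {"ewd": equal_width, "efd": equal_frequency}


def discretize(data: ExpressionMatrix, lam: int, method: str = "ewd") -> DiscretizedMatrix:
    """Dispatch to :func:`equal_width` (``"ewd"``) or :func:`equal_frequency` (``"efd"``)."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise CminetError(f"unknown discretization method {method!r}") from None
    return fn(data, lam)
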