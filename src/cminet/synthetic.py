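"""Seeded generators of ground-truth DAGs and linear-Gaussian SEM data.

The generators emulate DREAM3-style inputs: a known regulatory DAG and a
genes-in-rows expression matrix at the benchmark shapes (n genes x n
samples for the in-silico networks, 9 x 9 for the E. coli SOS module).  Data come from a linear structural equation
model: each gene is a signed, weighted sum of its regulators plus Gaussian
noise, optionally rescaled per gene to [0, 1] — an affine map that leaves
correlations, MI and CMI untouched.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .datamodel import CminetError, Dag, ExpressionMatrix

#: defaults chosen to give edge signals clearly separable from noise while
#: keeping indirect correlations nontrivial
DEFAULT_COEF_RANGE = (0.5, 1.5)
DEFAULT_NOISE_SD = 1.0


def generate_network(n_genes: int, n_edges: int, seed: int) -> Dag:
    """Uniform random DAG with exactly ``n_edges`` edges.

    A random permutation fixes a topological order; the edges are a uniform
    sample of the order-respecting pairs, so acyclicity holds by
    construction.
    """
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise CminetError(f"{n_edges} edges infeasible for {n_genes} genes "
                          f"(max {max_edges})")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    order = [genes[i] for i in rng.permutation(n_genes)]
    pairs = list(combinations(range(n_genes), 2))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    dag = Dag(genes)
    for c in chosen:
        i, j = pairs[int(c)]
        dag.add_edge(order[i], order[j])
    return dag


def simulate_expression(dag: Dag, n_samples: int,
                        coef_range: tuple[float, float] = DEFAULT_COEF_RANGE,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        seed: int = 0, rescale: bool = True) -> ExpressionMatrix:
    """Sample a linear-Gaussian SEM on ``dag``.

    Genes are sampled in topological order; edge coefficients have
    magnitude uniform in ``coef_range`` with random sign.  ``rescale``
    maps each gene affinely onto [0, 1], matching the range of the DREAM3
    benchmark matrices.
    """
    if noise_sd <= 0:
        raise CminetError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = list(dag.vertices)
    gidx = {g: i for i, g in enumerate(genes)}
    coefs = {(p, c): float(rng.uniform(*coef_range) * rng.choice([-1.0, 1.0]))
             for p, c in sorted(dag.directed_edges)}
    values = np.zeros((len(genes), n_samples))
    for g in dag.topological_order():
        noise = rng.normal(0.0, noise_sd, size=n_samples)
        total = noise
        for p in sorted(dag.parents(g)):
            total = total + coefs[(p, g)] * values[gidx[p]]
        values[gidx[g]] = total
    if rescale:
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        values = (values - lo) / span
    samples = [f"S{j + 1}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, values)


def sos_shape_fixture(seed: int = 2014) -> tuple[Dag, ExpressionMatrix]:
    """9 genes, 24-edge truth, 9 samples: the SOS-module benchmark shape."""
    dag = generate_network(9, 24, seed)
    data = simulate_expression(dag, 9, seed=seed + 1)
    return dag, data


_DREAM_EDGES = {10: 10, 50: 77, 100: 166}


def dream_shape_fixture(n: int, seed: int = 2014,
                        n_samples: int | None = None) -> tuple[Dag, ExpressionMatrix]:
    """n genes and n samples with the benchmark edge counts (10/77/166)."""
    if n not in _DREAM_EDGES:
        raise CminetError(f"n must be one of {sorted(_DREAM_EDGES)}")
    dag = generate_network(n, _DREAM_EDGES[n], seed)
    data = simulate_expression(dag, n_samples or n, seed=seed + 1)
    return dag, data
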