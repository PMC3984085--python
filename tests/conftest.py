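import numpy as np
import pytest

from cminet.datamodel import ExpressionMatrix


def make_expression(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 5 samples, hand-enterable values."""
    return make_expression([
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [2.0, 1.0, 4.0, 3.0, 6.0],
        [0.5, 0.5, 1.5, 1.0, 2.0],
    ])


def chain_data(n_samples: int, seed: int, coef: float = 1.0):
    """X -> Y -> Z linear-Gaussian chain with unit noise, unscaled."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_samples)
    y = coef * x + rng.normal(size=n_samples)
    z = coef * y + rng.normal(size=n_samples)
    return make_expression(np.stack([x, y, z]), genes=["X", "Y", "Z"])
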