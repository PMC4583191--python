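import numpy as np
import pytest

from ruvcoexp import ExpressionMatrix


def make_expr(values, centered=False, prefix="g"):
    """ExpressionMatrix from a raw (samples x genes) array with auto ids."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(
        values,
        [f"s{i}" for i in range(m)],
        [f"{prefix}{j}" for j in range(n)],
        centered=centered,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    return make_expr(rng.standard_normal((8, 12)))
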