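import numpy as np
import pytest

from ccadiff import ExpressionMatrix, SyntheticSpec, generate_pair


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """The 3x2 worked example used for hand-checking the chi-square formula."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ("gA", "gB", "gC"),
        ("s1", "s2"),
    )


@pytest.fixture
def random_matrix_factory():
    """Random strictly positive expression matrices of a given shape."""

    def make(k: int, p: int, seed: int) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            rng.uniform(0.5, 10.0, size=(k, p)),
            tuple(f"g{i}" for i in range(k)),
            tuple(f"s{j}" for j in range(p)),
        )

    return make


@pytest.fixture
def synthetic_pair():
    """Default four-class planted-marker pair with a full Th2 knockout."""
    spec = SyntheticSpec(seed=11, knockout=("Th2", 1.0))
    resource, test = generate_pair(spec)
    return spec, resource, test
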