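import numpy as np
import pandas as pd
import pytest

from snrs.matrix import ExpressionMatrix, GeneAnnotation
from snrs.pipeline import mini_config, tnbc_default_config
from snrs.simulate import simulate_expression


@pytest.fixture(scope="session")
def tnbc_data():
    """The default tumor scenario, simulated once per session."""
    config = tnbc_default_config(seed=11)
    expr, truth = simulate_expression(config)
    return config, expr, truth


@pytest.fixture(scope="session")
def mini_data():
    config = mini_config(seed=7)
    expr, truth = simulate_expression(config)
    return config, expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def toy_matrix():
    """4 genes x 3 cells counts matrix with hand-checkable values."""
    values = pd.DataFrame(
        [[0, 1, 15], [2, 2, 2], [10, 0, 3], [1, 3, 0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["c1", "c2", "c3"],
        dtype=float,
    )
    return ExpressionMatrix(values, state="counts")


def make_annotation(chrom_sizes: dict[str, int]) -> GeneAnnotation:
    """Annotation with genes named <chrom>_g<i> at increasing coordinates."""
    rows = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            rows.append((chrom, i * 1000, i * 1000 + 500, f"{chrom}_g{i:04d}"))
    return GeneAnnotation(pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"]))
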