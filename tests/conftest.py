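import numpy as np
import pytest

from cfnforest.evolution import GGGPConfig
from cfnforest.expression import ExpressionMatrix, LabelSet
from cfnforest.fnt import FunctionSet, GrammarSpec
from cfnforest.pso import PSOConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 genes with exactly one missing cell."""
    values = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
    return ExpressionMatrix(
        ["s1", "s2", "s3"], ["g1", "g2"], values, np.isnan(values)
    )


@pytest.fixture
def small_labels():
    return LabelSet(
        [f"s{i}" for i in range(8)],
        ["A", "A", "B", "B", "A", "B", "A", "B"],
    )


@pytest.fixture
def grammar():
    return GrammarSpec(FunctionSet((2, 3, 4)), input_dim=6, max_depth=4)


@pytest.fixture
def small_budgets():
    """GP/PSO budgets small enough for unit-test turnaround."""
    return (
        GGGPConfig(population_size=12, generations=5),
        PSOConfig(swarm_size=8, iterations=5),
    )


def random_valid_tree(grammar, rng):
    from cfnforest.evolution import random_tree

    return random_tree(grammar, rng)
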