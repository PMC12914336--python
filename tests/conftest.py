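import numpy as np
import pytest

from comodnet.datatypes import ExpressionMatrix, GeneSet, SampleGroups
from comodnet.synthetic import SyntheticSpec, simulate_disease_datasets


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def two_module_spec():
    """Two 50-gene planted modules shared by all diseases, 100 background."""
    return SyntheticSpec(
        n_genes=200,
        module_sizes=(50, 50),
        disease_modules=((0, 1), (0, 1), (0, 1)),
        seed=17,
    )


@pytest.fixture
def small_dataset(two_module_spec):
    datasets, truth = simulate_disease_datasets(two_module_spec)
    return datasets, truth


def make_expression(values, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        tuple(f"{gene_prefix}{i}" for i in range(n)),
        tuple(f"{sample_prefix}{j}" for j in range(m)),
        values,
    )


def make_groups(expr, n_case, name="disease"):
    labels = {}
    for j, s in enumerate(expr.sample_ids):
        labels[s] = "case" if j >= expr.n_samples - n_case else "control"
    return SampleGroups(name, labels)


@pytest.fixture
def gene_set_factory():
    return lambda name, genes: GeneSet.from_iterable(name, genes)
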