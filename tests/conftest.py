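import numpy as np
import pytest

from hdpclust import (
    ChainConfig,
    ExpressionMatrix,
    Hyperparameters,
    ObservationModel,
    worked_example,
)


@pytest.fixture
def two_gene_instance():
    """The two-gene, two-experiment illustrative instance: data, initial
    seating, standard-normal base measure, unit concentrations."""
    return worked_example()


@pytest.fixture
def std_model():
    return ObservationModel(obs_variance=1.0, prior_mean=0.0, prior_variance=1.0)


@pytest.fixture
def unit_hyper():
    return Hyperparameters(alpha0=1.0, alpha1=1.0)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        values=rng.normal(size=(3, 5)),
        gene_ids=tuple(f"g{i}" for i in range(5)),
        experiment_ids=tuple(f"e{j}" for j in range(3)),
    )
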