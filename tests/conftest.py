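import numpy as np
import pytest

from grtunfold import (
    CriteriaSet,
    GrtUnfoldingModel,
    IdealDistribution,
    ModelSpec,
    StimulusDistribution,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def spec_small():
    return ModelSpec.create(4, 2, 4)


@pytest.fixture
def model_small(spec_small):
    """Deterministic 4-stimulus, 2-dimension, 4-point-scale model."""
    means = np.array([[1.0, -0.5], [-1.0, 1.5], [0.5, 0.5], [0.0, 0.0]])
    stimuli = tuple(
        StimulusDistribution(stimulus_id=sid, mean=means[i])
        for i, sid in enumerate(spec_small.stimulus_ids)
    )
    ideal = IdealDistribution(
        mean=np.array([0.4, -0.2]),
        covariance=np.array([[1.2, -0.5], [-0.5, 2.0]]),
    )
    criteria = CriteriaSet(
        sensory=np.array([[-1.0, 0.0, 1.0], [-0.8, 0.3, 1.2]]),
        liking=np.array([4.0, 2.5, 1.2]),
    )
    return GrtUnfoldingModel(
        spec=spec_small, stimuli=stimuli, ideal=ideal, criteria=criteria
    )


def random_ideal(rng, n_dims):
    """Random positive-definite ideal distribution."""
    a = rng.normal(size=(n_dims, n_dims))
    cov = a @ a.T + 0.1 * np.eye(n_dims)
    return IdealDistribution(mean=rng.normal(size=n_dims), covariance=cov)
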