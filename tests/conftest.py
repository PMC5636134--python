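import numpy as np
import pytest

from codasmoke import LikelihoodPair, SimulationConfig


@pytest.fixture
def small_config():
    """Fast population: 100 agents, 12 months."""
    return SimulationConfig(
        p0=0.02,
        lik=LikelihoodPair(0.7, 0.8),
        n_agents=100,
        grid_shape=(10, 10),
        horizon_months=12,
        seed=123,
    )


@pytest.fixture
def default_config():
    """Study-scale configuration: 2500 agents, 72 months."""
    return SimulationConfig(p0=0.02, lik=LikelihoodPair(0.7, 0.8), seed=42)


def bayes_oracle(p, alpha, beta, observed, marginal):
    """Brute-force Bayes posterior from the joint probabilities.

    Builds both hypothesis probabilities through an explicit (arbitrary
    positive) marginal action probability and normalises — independent of
    the closed-form implementation; the marginal must cancel.
    """
    if observed == 1:
        num = alpha * p / marginal
        other = (1 - beta) * (1 - p) / marginal
    else:
        num = (1 - alpha) * p / marginal
        other = beta * (1 - p) / marginal
    return num / (num + other)


@pytest.fixture
def oracle():
    return bayes_oracle
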