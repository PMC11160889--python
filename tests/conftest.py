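import numpy as np
import pytest

from ethoscale import CohortSpec, StrategySpec, generate_cohort


def block_chain(n_states: int, eps: float, n_blocks: int = 2) -> np.ndarray:
    """Row-stochastic chain with equal blocks: mass 1-eps spread uniformly
    within the own block, eps spread uniformly over the rest."""
    P = np.zeros((n_states, n_states))
    size = n_states // n_blocks
    for i in range(n_states):
        b = i // size
        own = np.arange(b * size, (b + 1) * size)
        other = np.setdiff1d(np.arange(n_states), own)
        P[i, own] = (1.0 - eps) / size
        if other.size:
            P[i, other] = eps / other.size
        else:
            P[i, own] += eps / size
    return P


def block_labels(n_states: int, n_blocks: int) -> np.ndarray:
    return np.repeat(np.arange(n_blocks), n_states // n_blocks)


@pytest.fixture(scope="session")
def small_cohort():
    """Six fish, two planted groups differing in strategy dwell."""
    strategies = [
        StrategySpec(label=0, heading_sigma=8.0, speed_mean=4.0),
        StrategySpec(label=1, heading_sigma=70.0, speed_mean=14.0),
    ]
    chains = {
        0: np.array([[0.9, 0.1], [0.1, 0.9]]),
        1: np.array([[0.6, 0.4], [0.4, 0.6]]),
    }
    spec = CohortSpec(
        n_fish=6, bouts_per_fish=500, strategies=strategies,
        strategy_chains=chains, group_assignment=[0, 1, 0, 1, 0, 1],
        context_labels=["a", "a", "a", "b", "b", "b"], frames_per_bout=12, seed=7,
    )
    return generate_cohort(spec)
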