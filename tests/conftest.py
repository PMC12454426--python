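import itertools

import numpy as np
import pytest

from carbongame.params import PARAM_NAMES, GameParameters, baseline_parameters
from carbongame.payoffs import build_payoff_tensor


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def baseline_tensor(baseline):
    return build_payoff_tensor(baseline)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_params(rng, lo=0.1, hi=9.9):
    draws = {name: float(rng.uniform(lo, hi)) for name in PARAM_NAMES if name != "alpha"}
    draws["alpha"] = float(rng.uniform(0.05, 0.95))
    return GameParameters(**draws)


def oracle_rates(tensor, state):
    """Brute-force replicator rates: enumerate all 16 pure profiles.

    Independent of the package's expected-payoff path: computes each
    player's conditional expected payoffs by summing full profile
    probabilities, then uses p * (E_active - E_average).
    """
    state = np.asarray(state, dtype=float)
    rates = np.zeros(4)
    for i in range(4):
        e_active = 0.0
        e_average = 0.0
        for profile in itertools.product((0, 1), repeat=4):
            prob_others = 1.0
            for j, bit in enumerate(profile):
                if j != i:
                    prob_others *= state[j] if bit else 1.0 - state[j]
            payoff = tensor.values[(i, *profile)]
            prob_own = state[i] if profile[i] else 1.0 - state[i]
            e_average += prob_others * prob_own * payoff
            if profile[i] == 1:
                e_active += prob_others * payoff
        rates[i] = state[i] * (e_active - e_average)
    return rates
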