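import numpy as np
import pytest

from glct import RateRoutingRep


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_rate_routing(n: int, m: int, rng: np.random.Generator,
                        self_loops: bool = False) -> RateRoutingRep:
    """A random valid rate/routing representation (optionally loop-free)."""
    rates = 10.0 ** rng.uniform(-1, 1, n)
    rows = rng.dirichlet(np.ones(n + m), size=n)
    if not self_loops:
        rows[np.arange(n), np.arange(n)] = 0.0
        rows /= rows.sum(axis=1, keepdims=True)
    return RateRoutingRep(initial=rng.dirichlet(np.ones(n)), rates=rates,
                          within=rows[:, :n], exit=rows[:, n:])
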