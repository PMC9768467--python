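import numpy as np
import pytest

from rfmnet import NetworkSpec, PoolFunction, RateProfile

#: coarse-grained rates of a real yeast gene (length-5 chain), used as the
#: standard heterogeneous worked example throughout the suite
YEAST_RATES = (0.1678, 0.2572, 0.2758, 0.2514, 0.2612, 0.3002)


@pytest.fixture
def yeast_profile() -> RateProfile:
    return RateProfile(YEAST_RATES)


@pytest.fixture
def homogeneous_two_site() -> RateProfile:
    return RateProfile((1.0, 1.0, 1.0))


def random_profile(rng: np.random.Generator, max_n: int = 8) -> RateProfile:
    n = int(rng.integers(1, max_n + 1))
    rates = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=n + 1))
    return RateProfile(rates)


def random_network(rng: np.random.Generator, max_m: int = 5, max_n: int = 6) -> NetworkSpec:
    m = int(rng.integers(1, max_m + 1))
    chains = [
        (
            random_profile(rng, max_n=max_n),
            PoolFunction.linear(float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))),
        )
        for _ in range(m)
    ]
    return NetworkSpec.from_chains(chains, s=float(rng.uniform(1.0, 10.0)))
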