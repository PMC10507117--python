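import numpy as np
import pytest

from pollinet import Community, PlantParams, PollinatorParams, default_distributions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dists():
    return default_distributions()


def make_plant(**kw) -> PlantParams:
    base = dict(g=0.4, u=0.1, w=0.3, beta=0.4, phi=0.04, eps=1.0, mu_P=0.01, e=0.8)
    base.update(kw)
    return PlantParams(**base)


def make_pollinator(**kw) -> PollinatorParams:
    base = dict(tau=1.0, c=0.2, b=0.4, mu_A=0.001, G=30.0)
    base.update(kw)
    return PollinatorParams(**base)


@pytest.fixture
def pair_community():
    """One plant linked to one specialist pollinator, near introduction."""
    comm = Community.empty()
    comm.add_plant("P1", make_plant(), 0.05)
    comm.add_pollinator("A1", make_pollinator(), 0.05, [0])
    return comm


def random_community(rng, n_p=3, n_a=3, connect=0.7):
    """Small random community with normalized efforts and positive state."""
    dists = default_distributions()
    comm = Community.empty()
    for i in range(n_p):
        comm.add_plant(f"P{i}", dists.sample_plant(rng), float(rng.uniform(0.1, 2.0)))
    for j in range(n_a):
        linked = [i for i in range(n_p) if rng.random() < connect]
        if not linked:
            linked = [int(rng.integers(n_p))]
        comm.add_pollinator(
            f"A{j}", dists.sample_pollinator(rng), float(rng.uniform(0.1, 5.0)), linked
        )
    # randomize efforts away from the uniform initialization
    w = np.where(comm.adjacency, rng.uniform(0.2, 1.0, comm.alpha.shape), 0.0)
    comm.alpha = w
    comm.normalize_efforts()
    comm.R = rng.uniform(0.0, 0.5, n_p)
    return comm
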