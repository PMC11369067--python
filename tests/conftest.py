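import numpy as np
import pytest

from engraftkit import synthetic_cohort as sc


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (2 donors, 24 recipients), scored once per session."""
    from engraftkit import pipeline

    cfg = sc.SimulationConfig(seed=11)
    sim = sc.simulate_cohort(cfg)
    result = pipeline.score_cohort(sim.profiles, sim.metadata)
    return sim, result


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_composition(rng, n, allow_zero=False):
    x = rng.dirichlet(np.full(n, 0.7))
    if allow_zero:
        mask = rng.random(n) < 0.3
        if mask.all():
            mask[0] = False
        x = np.where(mask, 0.0, x)
        x = x / x.sum()
    return x
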