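from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitorecomb as mr

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def paper_scene():
    """The default planted scenario, discovered and enumerated once.

    genome: 100-kb circle with the planted repeat geometry; catalog: what
    the finder recovers; forms: closure under the two long repeat pairs.
    """
    genome, truth = mr.make_genome(
        mr.PAPER_LIKE_TOTAL_LEN, mr.paper_like_repeats(), seed=1
    )
    catalog = mr.find_dispersed_repeats(genome)
    active = [p for p in catalog.all_pairs() if not p.shadowed and p.length >= 1000]
    forms = {
        f.name: f for f in mr.enumerate_forms(genome, catalog, active, max_events=2)
    }
    return SimpleNamespace(
        genome=genome, truth=truth, catalog=catalog, active=active, forms=forms
    )
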