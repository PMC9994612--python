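import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from mitorder.datasets import load_annotation  # noqa: E402
from mitorder.gene_order import extract_order  # noqa: E402
from mitorder.synthetic import (SimulationConfig, simulate_genome,  # noqa: E402
                                simulate_history)


@pytest.fixture(scope="session")
def chishuiense():
    return load_annotation("chishuiense")


@pytest.fixture(scope="session")
def wushanense():
    return load_annotation("wushanense")


@pytest.fixture(scope="session")
def chishuiense_order(chishuiense):
    return extract_order(chishuiense)


@pytest.fixture(scope="session")
def wushanense_order(wushanense):
    return extract_order(wushanense)


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic simulated genome with sequence (no overlaps, so
    codon-level checks are exact)."""
    cfg = SimulationConfig(seed=7, events=1, overlap_prob=0.0)
    rng = cfg.rng()
    order, history = simulate_history(cfg, rng)
    ann = simulate_genome(order, cfg, rng)
    return ann, order, history, cfg
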