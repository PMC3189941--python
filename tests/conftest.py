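"""Shared fixtures: small simulated worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from orthodiv import SimulationConfig, simulate_transcriptomes


@pytest.fixture(scope="session")
def small_world():
    """60 clean ortholog pairs at ~1% divergence, no paralogs."""
    cfg = SimulationConfig(n_transcripts=60, branch_divergence=0.01,
                           paralog_fraction=0.0, seed=101)
    return simulate_transcriptomes(cfg)


@pytest.fixture(scope="session")
def paralog_world():
    """60 pairs with a 10% paralog spike in species A."""
    cfg = SimulationConfig(n_transcripts=60, branch_divergence=0.01,
                           paralog_fraction=0.1, seed=202)
    return simulate_transcriptomes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
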