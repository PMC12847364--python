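"""Shared fixtures: reduced-scale synthetic sessions reused across tests.

The reduced protocol keeps the full 7-task structure and trial timing but
shrinks trial counts and the montage so a full simulate -> preprocess ->
decode cycle runs in seconds.  Session-scoped fixtures are treated as
read-only by the tests that share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from sibci.config import AnalysisConfig, ProtocolConfig, SimConfig
from sibci.preprocess import preprocess
from sibci.simulate import simulate_session


@pytest.fixture(scope="session")
def tiny_protocol() -> ProtocolConfig:
    """7 tasks x 5 trials/block x 2 blocks on a 16-channel montage."""
    return ProtocolConfig(trials_per_task_per_block=5, n_blocks=2, n_channels=16)


@pytest.fixture(scope="session")
def fast_analysis() -> AnalysisConfig:
    """Default analysis constants with only the repeat count reduced."""
    return AnalysisConfig(n_repeats=2)


@pytest.fixture(scope="session")
def strong_sim() -> SimConfig:
    """Large effect, every trial self-rated correct (no degraded trials)."""
    return SimConfig(effect_size=1.0, self_eval_probs=(1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def tiny_session(tiny_protocol, strong_sim):
    """(raw, subjective, plan) for the reduced protocol at strong effect."""
    return simulate_session(tiny_protocol, strong_sim, seed=20407)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_session, fast_analysis):
    raw, subjective, plan = tiny_session
    return preprocess(raw, fast_analysis, plan=plan, subjective=subjective)


@pytest.fixture(scope="session")
def null_epochs(tiny_protocol, fast_analysis):
    """Epochs from a zero-effect session: no task information by construction."""
    sim = SimConfig(effect_size=0.0, self_eval_probs=(1.0, 0.0, 0.0))
    raw, subjective, plan = simulate_session(tiny_protocol, sim, seed=515)
    return preprocess(raw, fast_analysis, plan=plan, subjective=subjective)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
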