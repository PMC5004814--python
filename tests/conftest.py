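"""Shared fixtures: sequence library and seeded synthetic sessions.

Expensive simulations and decoder evaluations are session-scoped so that
module tests and the end-to-end checks share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from vibroseq.decoder import BinSpec, binned_counts, evaluate_stimulus_decoder
from vibroseq.stimulus import load_sequence_library
from vibroseq.synthetic import SessionConfig, generate_session

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return load_sequence_library()


@pytest.fixture(scope="session")
def default_session():
    """Default mixed-archetype session (30 units, 50 trials/stimulus)."""
    return generate_session(SessionConfig(seed=1))


@pytest.fixture(scope="session")
def fast_session():
    """Pure Fast-archetype population for stimulus-decoding benchmarks."""
    return generate_session(
        SessionConfig(seed=3, unit_counts=(("Fast", 16),), n_trials_per_stimulus=50)
    )


@pytest.fixture(scope="session")
def slowpos_session():
    """Pure SlowPos population for choice-decoding benchmarks."""
    return generate_session(
        SessionConfig(seed=5, unit_counts=(("SlowPos", 12),), n_trials_per_stimulus=50)
    )


@pytest.fixture(scope="session")
def fast_binned(fast_session):
    return binned_counts(fast_session, BinSpec())


@pytest.fixture(scope="session")
def fast_stim_report(fast_session, fast_binned):
    labels = fast_session.trials["stimulus"].to_numpy()
    return evaluate_stimulus_decoder(fast_binned, labels, n_repeats=20, seed=0)
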