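"""Shared fixtures: seeded synthetic sessions at the study's scale.

The expensive session-level fixtures are module-agnostic and session-scoped
so simulation and preprocessing run once per pytest invocation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import mibci

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return mibci.default_montage()


@pytest.fixture(scope="session")
def erd_session():
    """Full-scale session with strong planted contralateral ERD."""
    cfg = mibci.SimulationConfig(seed=11)  # depth 0.7, snr 2 defaults
    rec, internals = mibci.simulate_session(cfg, return_internals=True)
    return cfg, rec, internals


@pytest.fixture(scope="session")
def erd_epochs(erd_session):
    """Preprocessed (band-pass + notch + CAR) epochs of the ERD session."""
    _, rec, _ = erd_session
    return mibci.extract_epochs(mibci.preprocess(rec))


@pytest.fixture(scope="session")
def small_epochs():
    """Cheap 12-trials-per-class session for combinatorial tests."""
    cfg = mibci.SimulationConfig(seed=5, n_trials_per_class=12)
    rec = mibci.simulate_session(cfg)
    return mibci.extract_epochs(mibci.preprocess(rec))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
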