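import numpy as np
import pytest

from neurochron import (
    ConcentrationSeries,
    NeurochemParams,
    ObserverParams,
    TaskConfig,
    generate_session,
)


@pytest.fixture(scope="session")
def default_session():
    """One default 300-trial session with sweeps, reused across read-only tests."""
    return generate_session(seed=11)


@pytest.fixture(scope="session")
def truth_series(default_session):
    """Ground-truth concentration series (bypasses the decoder)."""
    rec = default_session
    return ConcentrationSeries(rec.timestamps, rec.truth_da, rec.truth_5ht)


@pytest.fixture
def coupled_session():
    """Session with strong phasic and tonic couplings, no sweep synthesis."""
    return generate_session(
        observer=ObserverParams(phasic_coupling=0.08, tonic_coupling=0.3),
        seed=21,
        include_sweeps=False,
    )


def behaviour_session(seed, **observer_kwargs):
    """Sweep-free session for behaviour-only simulations."""
    return generate_session(
        observer=ObserverParams(**observer_kwargs), seed=seed, include_sweeps=False
    )
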