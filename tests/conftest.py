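"""Shared fixtures: synthetic sessions in the configurations tests reuse."""

import numpy as np
import pytest

import physiofmri as pf


@pytest.fixture(scope="session")
def default_session():
    """A full-size session at the default study conditions."""
    return pf.generate_session(pf.GroundTruth(seed=101))


@pytest.fixture(scope="session")
def noiseless_clean_session():
    """No noise, no physiological contamination: pure task + baseline."""
    truth = pf.GroundTruth(seed=102, noise_sd=0.0, cardiac_gain=0.0,
                           resp_gain=0.0, rvt_gain=0.0,
                           beta_cc=1.0, beta_ic=2.0, blink_rate=0.0)
    return pf.generate_session(truth)


@pytest.fixture(scope="session")
def noiseless_contaminated_session():
    """No thermal noise, cardiac + respiratory + RVT contamination only."""
    truth = pf.GroundTruth(seed=103, noise_sd=0.0, beta_cc=0.0, beta_ic=0.0)
    return pf.generate_session(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def trimmed(session):
    """Session pieces in retained-scan time (first four volumes dropped)."""
    bold = session.bold.discard_initial(4)
    events = session.events.shifted(-4 * session.bold.tr_s)
    physio = pf.sync_to_scan(session.physio, session.bold.n_volumes,
                             session.bold.tr_s)
    return bold, events, physio
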