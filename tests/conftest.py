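import numpy as np
import pytest

import relpa


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete study configuration."""
    return relpa.SimulationConfig(n_participants=5, n_sessions=2, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return relpa.simulate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_study):
    kept, _ = relpa.filter_trials(tiny_study.records)
    return relpa.extract_matrix(kept, tiny_study.participants)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_record(
    hr=None,
    rr=None,
    eda=None,
    temp=None,
    rpe=13,
    participant_id="PX",
    status="complete",
):
    """Hand-built trial record for unit tests."""
    empty = np.asarray([], dtype=float)
    return relpa.TrialRecord(
        participant_id=participant_id,
        session_index=1,
        trial_type="brisk_walk",
        hr=np.asarray(hr, dtype=float) if hr is not None else empty,
        rr=np.asarray(rr, dtype=float) if rr is not None else empty,
        eda=np.asarray(eda, dtype=float) if eda is not None else empty,
        temp=np.asarray(temp, dtype=float) if temp is not None else empty,
        rpe=rpe,
        status=status,
    )
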