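import pytest
from hypothesis import settings

from trialchain import TrialConfig, run_trial, verify_trial

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL = TrialConfig(n_participants=6, records_per_participant=4,
                    dropout_probability=0.0)


@pytest.fixture(scope="session")
def small_run():
    """One honest small trial shared by read-only tests."""
    return run_trial(SMALL, seed=11)


@pytest.fixture(scope="session")
def small_report(small_run):
    return verify_trial(small_run.ledger)


@pytest.fixture(scope="session")
def headline_run():
    """The full-size honest trial: 100 participants x 10 records, all
    completing (the verification protocol targets completed participants)."""
    config = TrialConfig(n_participants=100, records_per_participant=10,
                         dropout_probability=0.0)
    return run_trial(config, seed=20190501)
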