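import warnings

import pandas as pd
import pytest

from soarharness.io_formats import SessionRecord
from soarharness.synthetic_flight import SimConfig, simulate_session, simulate_study


def make_session_record(harness="backpack", session_id="s0001", duration_s=600,
                        individual_id="ind01", species="griffon_vulture"):
    start = pd.Timestamp("2018-06-25T08:00:00", tz="UTC")
    return SessionRecord(
        session_id=session_id,
        individual_id=individual_id,
        species=species,
        harness=harness,
        date=start.date(),
        start_time=start,
        end_time=start + pd.Timedelta(seconds=duration_s),
        device_id="dev01",
    )


@pytest.fixture(scope="session")
def short_config():
    return SimConfig(n_days=1, sessions_per_day=2, session_duration=600,
                     session_skip_prob=0.3, seed=42)


@pytest.fixture(scope="session")
def one_session():
    """One deterministic 10-minute backpack session with truth channel.

    Flapping bouts are frequent enough that both activity classes occur.
    """
    config = SimConfig(session_duration=600, flap_bout_prob=0.5, seed=42)
    record = make_session_record()
    gps, acc, truth = simulate_session(config, record, rng_seed=7)
    assert (truth.data["true_class"].str.startswith("active")).any()
    return record, gps, acc, truth


@pytest.fixture(scope="session")
def mini_study():
    """A small multi-session study plus its processed tables."""
    from soarharness.pipeline import process_study
    from soarharness.synthetic_flight import wind_table_for_study

    config = SimConfig(n_days=2, sessions_per_day=3, session_duration=600,
                       session_skip_prob=0.3, seed=1)
    study = simulate_study(config)
    wind = wind_table_for_study(study)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        segments, sessions_df = process_study(
            ((s.gps, s.acc) for s in study.sessions), wind=wind
        )
    return study, segments, sessions_df
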