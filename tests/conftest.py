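import numpy as np
import pandas as pd
import pytest

import reeftrace as rt


@pytest.fixture(scope="session")
def sim():
    """One moderate synthetic telemetry study shared across tests."""
    cfg = rt.simulate.TelemetrySimConfig(n_sharks=12, study_days=420)
    return rt.simulate.simulate_telemetry(cfg, seed=2024)


@pytest.fixture(scope="session")
def pipeline(sim):
    """(strings, presence, summary rows) derived from the shared simulation."""
    strings = rt.filtering.build_strings(sim.detections)
    presence = rt.filtering.daily_presence(strings, sim.tags, sim.receivers)
    rows = rt.detmodel.build_summary(presence, sim.tags, sim.receivers)
    return strings, presence, rows


@pytest.fixture(scope="session")
def glover():
    """(metrics, tags) of the packaged 33-shark monitoring table."""
    return rt.fidelity.glover_metrics()


def make_detections(records):
    """detections DataFrame from (seconds_offset, receiver, transmitter) triples."""
    t0 = pd.Timestamp("2005-06-01 06:00:00")
    return pd.DataFrame({
        "timestamp": [t0 + pd.Timedelta(seconds=s) for s, _, _ in records],
        "receiver_id": [r for _, r, _ in records],
        "transmitter_id": [t for _, _, t in records],
    })
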