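"""Shared fixtures: one synthetic network realization reused across tests."""

import pytest

from baycarb import synth
from baycarb.pipeline import run_trend_pipeline


@pytest.fixture(scope="session")
def nb_config():
    return synth.nb_like(seed=7)


@pytest.fixture(scope="session")
def nb_network(nb_config):
    """One bay-like realization: (records in reader layout, truth ledger)."""
    records, ledger = synth.generate_network(nb_config)
    records = records.rename(columns={"station": "station_id", "pH": "pH_nbs"})
    return records, ledger


@pytest.fixture(scope="session")
def analysis_stations(nb_config):
    """The bay-wide averaging set: every station except the river one."""
    return [s.station_id for s in nb_config.stations if s.station_id != "PD"]


@pytest.fixture(scope="session")
def nb_pipeline(nb_network, analysis_stations):
    records, _ = nb_network
    return run_trend_pipeline(records, analysis_stations=analysis_stations)
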