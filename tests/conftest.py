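import pytest

from kirpore.pore_model import default_geometry
from kirpore.synthetic import scenario_preset, simulate


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def wt_run():
    """A moderate stably-open WT permeation run shared across tests."""
    sc = scenario_preset("WT", voltage=310.0, stably_open=True)
    bundle, log = simulate(sc.model, sc.gate, None, duration=10.0, seed=5,
                           include_gate_atoms=False)
    return sc, bundle, log, bundle.to_track_table()


@pytest.fixture(scope="session")
def blocked_run():
    """WT + SPM blocker at +215 mV with a deep-binding event."""
    sc = scenario_preset("WT", voltage=215.0, stably_open=True)
    bundle, log = simulate(sc.model, sc.gate, sc.blocker, duration=4.0,
                           seed=200, dt_ns=3.0, include_gate_atoms=False)
    return sc, bundle, log, bundle.to_track_table()
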