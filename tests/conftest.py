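import numpy as np
import pytest

from peptidepore import simulate as sim


@pytest.fixture(scope="session")
def butter_sos():
    from scipy import signal as sps
    return sps.butter(4, 4000.0, btype="low", fs=20000.0, output="sos")


@pytest.fixture(scope="session")
def filtered_noise_sd(butter_sos):
    """Empirical SD reduction of unit white noise through the 4 kHz filter.

    Serves as the independent oracle for every test that compares a
    measured SD against an injected (pre-filter) noise SD.
    """
    from scipy import signal as sps
    rng = np.random.default_rng(987654)
    return float(sps.sosfiltfilt(butter_sos, rng.standard_normal(2_000_000)).std())


@pytest.fixture()
def step_trace():
    """One clean simulated step event (G = 1.1 nS at +100 mV)."""
    cfg = sim.SimulationConfig(
        voltage=100.0, duration_s=6.0,
        open_events=[sim.archetype_event("step", 1.1)], seed=42)
    return sim.simulate_trace(cfg)


@pytest.fixture()
def mixed_trace():
    """One trace containing all four opening archetypes."""
    events = [sim.archetype_event(a) for a in sim.ARCHETYPES]
    total = 1.5 + sum(e.duration_s + 1.5 for e in events) + 1.0
    cfg = sim.SimulationConfig(voltage=100.0, duration_s=total,
                               open_events=events, seed=7)
    return sim.simulate_trace(cfg)
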