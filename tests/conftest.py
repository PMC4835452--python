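import numpy as np
import pytest

from tmasim import HHParams, SimConfig, preset_sweep, run_sweep, simulate


@pytest.fixture(scope="session")
def params():
    return HHParams()


@pytest.fixture(scope="session")
def const15_result(params):
    """Suprathreshold constant-current run reused across tests."""
    return simulate(params, 15.0, SimConfig(duration=500.0, dt=1e-3))


@pytest.fixture(scope="session")
def sweep_table(params):
    """Factory for (cached) smoke-grid sweep tables of the named presets."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = run_sweep(preset_sweep(name, smoke=True), params)
        return cache[name]

    return get


@pytest.fixture
def bump_trace():
    """Synthetic trace with three 80 mV Gaussian bumps at 20/30/40 ms."""
    t = np.arange(0.0, 60.0, 0.01)
    v = np.zeros_like(t)
    centers = np.array([20.0, 30.0, 40.0])
    for c in centers:
        v += 80.0 * np.exp(-0.5 * ((t - c) / 0.5) ** 2)

    class Trace:
        pass

    tr = Trace()
    tr.t, tr.v, tr.centers = t, v, centers
    return tr
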