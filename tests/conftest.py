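import warnings

import pytest

from volcert import bench, device, features


@pytest.fixture(scope="session")
def default_events():
    """The default synthetic bench: 44 formulations measured once each."""
    forms = device.generate_formulation_set(seed=7)
    pump = device.PumpModel(seed=7)
    return device.simulate_measurements(forms, pump, seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_events):
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # no event may be silently short
        return features.build_dataset(default_events)


@pytest.fixture(scope="session")
def bench_result(default_dataset):
    """One full five-regressor bench at the default seeds (shared: ~1 min)."""
    return bench.run_bench(default_dataset)


@pytest.fixture()
def light_nn_specs():
    """Bench specs with a cut-down network budget for fast unit tests."""
    light = {"n_members": 2, "epochs": 300, "patience": 60}
    return [
        bench.RegressorSpec("linear"),
        bench.RegressorSpec("neural_net", dict(light)),
        bench.RegressorSpec("decision_tree"),
    ]
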