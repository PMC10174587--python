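import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from volcert import device
from volcert.device import (
    DEFAULT_MARBLES,
    Formulation,
    MeasurementCycle,
    ProtocolError,
    PulsePattern,
    PumpModel,
    SensorRangeError,
    generate_formulation_set,
    measure_object,
    read_events_csv,
    run_measurement_cycle,
    simulate_measurements,
    simulate_slot_sequence,
    sphere_volume,
    write_events_csv,
)

QUIET = PumpModel(jitter_std=0.0, steady_rel_std=0.0, start_rel_std=0.0)


def _formulation(volume):
    return Formulation("Fx", ("m",), volume)


class TestSphereVolume:
    @pytest.mark.parametrize(
        "diameter, expected, tol",
        [(0.0, 0.0, 1e-12), (10.0, 523.5988, 1e-3), (24.1, 7329.0, 0.1)],
    )
    def test_values(self, diameter, expected, tol):
        assert sphere_volume(diameter) == pytest.approx(expected, abs=tol)

    def test_inverse_recovers_smallest_marble_diameter(self):
        # bisection on the volume formula: which diameter yields 7329 mm^3?
        d = brentq(lambda x: sphere_volume(x) - 7329.0, 1.0, 100.0)
        assert d == pytest.approx(24.1, abs=5e-3)  # the caliper reading

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume(-1.0)


class TestMarblesAndFormulations:
    def test_default_marbles_reproduce_recorded_volumes(self):
        got = {m.id: round(m.volume / 1000.0, 1) for m in DEFAULT_MARBLES}
        assert got == {"Ma1": 8.1, "Ma2": 8.0, "Ma3": 7.3, "Ma4": 7.6,
                       "Ma5": 7.9, "Ma6": 16.1, "Ma7": 23.4, "Ma8": 60.1}

    def test_inconsistent_marble_volume_rejected(self):
        with pytest.raises(ValueError):
            device.MarbleSpec("bad", diameter=10.0, volume=9999.0)

    def test_formulation_volume_is_sum_of_members(self):
        f = Formulation.from_marbles("F", DEFAULT_MARBLES[:3])
        assert f.true_volume == pytest.approx(
            sum(m.volume for m in DEFAULT_MARBLES[:3])
        )

    def test_empty_formulation_rejected(self):
        with pytest.raises(ValueError):
            Formulation.from_marbles("F", [])


class TestSlotSequence:
    def test_quiet_equal_rates_give_constant_slots(self):
        pump = PumpModel(ts_start=0.03, ts_steady=0.03, jitter_std=0.0,
                         steady_rel_std=0.0, start_rel_std=0.0)
        slots = simulate_slot_sequence(pump, 50)
        assert np.all(slots == 0.03)

    def test_tiny_tau_plateaus_immediately(self):
        pump = PumpModel(ts_start=0.037, ts_steady=0.028, tau=1e-9,
                         jitter_std=0.0, steady_rel_std=0.0, start_rel_std=0.0)
        slots = simulate_slot_sequence(pump, 200)
        assert slots[0] == pytest.approx(0.037)
        assert np.all(slots[1:] == pytest.approx(0.028))
        assert slots.mean() == pytest.approx(0.028, rel=2e-3)

    def test_deterministic_given_seed(self):
        pump = PumpModel(seed=5)
        a = simulate_slot_sequence(pump, 100)
        b = simulate_slot_sequence(pump, 100)
        assert np.array_equal(a, b)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 300))
    def test_slots_respect_clipping_envelope(self, seed, n):
        pump = PumpModel(seed=seed)
        slots = simulate_slot_sequence(pump, n)
        lo = max(pump.ts_steady / 10, pump.ts_steady - 5 * pump.noise_scale)
        hi = pump.ts_start + 5 * pump.noise_scale
        assert np.all(slots >= lo - 1e-12) and np.all(slots <= hi + 1e-12)

    def test_pump_invariants_enforced(self):
        with pytest.raises(ValueError):
            PumpModel(ts_start=0.02, ts_steady=0.03)
        with pytest.raises(ValueError):
            PumpModel(tau=0.0)
        with pytest.raises(ValueError):
            PumpModel(jitter_std=-1e-3)


class TestMeasureObject:
    @pytest.mark.parametrize("volume, pulses",
                             [(60100.0, 445), (8100.0, 60), (135.0, 1)])
    def test_ideal_sensor_counts(self, volume, pulses):
        event = measure_object(_formulation(volume), QUIET,
                               ml_per_pulse=0.135, flux_exponent=0.0)
        assert event.pattern.n_pulses == pulses

    def test_below_one_quantum_rejected(self):
        with pytest.raises(SensorRangeError):
            measure_object(_formulation(50.0), QUIET, ml_per_pulse=0.135,
                           flux_exponent=0.0)

    def test_volume_conserved_within_one_effective_quantum(self, default_events):
        for event in default_events:
            quantum = 1000.0 * event.effective_ml_per_pulse
            recovered = event.pattern.n_pulses * quantum
            assert abs(recovered - event.true_volume) <= quantum

    def test_effective_calibration_tracks_flow(self):
        # slower steady flow (longer slots) must lower the volume per pulse
        slow = PumpModel(ts_start=0.034, ts_steady=0.032, jitter_std=0.0,
                         steady_rel_std=0.0, start_rel_std=0.0)
        fast = PumpModel(ts_start=0.031, ts_steady=0.029, jitter_std=0.0,
                         steady_rel_std=0.0, start_rel_std=0.0)
        f = _formulation(30000.0)
        e_slow = measure_object(f, slow)
        e_fast = measure_object(f, fast)
        assert e_slow.effective_ml_per_pulse < e_fast.effective_ml_per_pulse


class TestPulsePattern:
    def test_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            PulsePattern(np.array([0.0, 0.03, 0.03]))

    def test_first_pulse_at_zero_required(self):
        with pytest.raises(ValueError):
            PulsePattern(np.array([0.1, 0.2]))

    def test_flux_outside_sensor_range_rejected(self):
        # 1 s slots at 0.135 ml/pulse -> 0.0081 L/min, below the 0.1 floor
        with pytest.raises(SensorRangeError):
            PulsePattern(np.array([0.0, 1.0, 2.0]))


class TestMeasurementCycle:
    def _happy(self, formulation):
        return ["fill", "zero", ("submerge", formulation), "drain"]

    def test_canonical_sequence_appends_one_event(self):
        log = run_measurement_cycle(self._happy(_formulation(20000.0)),
                                    pump=QUIET)
        assert len(log) == 1
        assert log[0].true_volume == 20000.0

    def test_empty_command_stream_yields_empty_log(self):
        assert run_measurement_cycle([]) == []

    def test_double_submerge_raises_protocol_error(self):
        cycle = MeasurementCycle(pump=QUIET)
        cycle.process("fill")
        cycle.process("zero")
        cycle.process(("submerge", _formulation(20000.0)))
        with pytest.raises(ProtocolError):
            cycle.process(("submerge", _formulation(30000.0)))

    def test_submerge_before_zero_raises(self):
        cycle = MeasurementCycle(pump=QUIET)
        cycle.process("fill")
        with pytest.raises(ProtocolError):
            cycle.process(("submerge", _formulation(20000.0)))

    def test_drain_at_zero_level_is_noop(self):
        cycle = MeasurementCycle(pump=QUIET)
        cycle.process("drain")
        cycle.process("fill")
        cycle.process("zero")
        cycle.process("drain")
        assert cycle.log == []

    def test_two_full_cycles(self):
        f1, f2 = _formulation(20000.0), _formulation(40000.0)
        cycle = MeasurementCycle(pump=QUIET)
        cycle.run(["fill", "zero", ("submerge", f1), "drain",
                   ("submerge", f2), "drain"])
        assert [e.true_volume for e in cycle.log] == [20000.0, 40000.0]


class TestFormulationSet:
    def test_default_set_size_and_volume_span(self):
        forms = generate_formulation_set(seed=3)
        volumes = np.array([f.true_volume for f in forms])
        single = [m.volume for m in DEFAULT_MARBLES]
        assert len(forms) == 44
        assert volumes.min() == pytest.approx(min(single))
        assert volumes.max() <= max(single) + 1.0
        assert len({f.id for f in forms}) == 44

    def test_singleton_request(self):
        forms = generate_formulation_set(DEFAULT_MARBLES[:1], n_formulations=1)
        assert forms[0].marble_ids == ("Ma1",)

    def test_seed_sensitivity_and_reproducibility(self):
        a = generate_formulation_set(seed=1)
        b = generate_formulation_set(seed=2)
        c = generate_formulation_set(seed=1)
        assert [f.marble_ids for f in a] != [f.marble_ids for f in b]
        assert [f.marble_ids for f in a] == [f.marble_ids for f in c]

    def test_empty_marble_list_rejected(self):
        with pytest.raises(ValueError):
            generate_formulation_set([], 5)


def test_same_seed_gives_bit_identical_event_logs():
    forms = generate_formulation_set(seed=4, n_formulations=6)
    a = simulate_measurements(forms, PumpModel(seed=4), seed=4)
    b = simulate_measurements(forms, PumpModel(seed=4), seed=4)
    for ea, eb in zip(a, b):
        assert np.array_equal(ea.pattern.timestamps, eb.pattern.timestamps)
        assert ea.effective_ml_per_pulse == eb.effective_ml_per_pulse


def test_events_csv_round_trip(tmp_path, default_events):
    write_events_csv(default_events[:5], tmp_path)
    back = read_events_csv(tmp_path)
    assert len(back) == 5
    for orig, rt in zip(default_events[:5], back):
        assert rt.formulation_id == orig.formulation_id
        assert rt.true_volume == pytest.approx(orig.true_volume)
        np.testing.assert_allclose(rt.pattern.timestamps,
                                   orig.pattern.timestamps, atol=1e-12)
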