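"""Simulation of the water-displacement (WD) volumetry device.

The physical device measures the volume of an irregular submerged object by
pumping the displaced water through a turbine flow sensor that emits one
TTL pulse per water quantum.  Two instabilities dominate the recorded
tuning data and are both modeled here:

* **pump timing** — inter-pulse intervals ("time slots") start long and
  decay exponentially toward a steady value; the steady value itself varies
  from run to run (the pump "tends to stabilize itself" but never repeats),
  and a smooth slow wander rides on top within a run;
* **flux-dependent sensor calibration** — the volume represented by one
  pulse is not constant: it falls as the flow slows,
  ``q = q0 * (slot_nominal / slot)**gamma``.  The recorded tuning events
  show effective ml/pulse between 0.11 and 0.14, strongly anti-correlated
  with the event's mean slot, which is why volume cannot be read off the
  pulse count alone and must be regressed from the whole pulse pattern.

A third noise term, white timing jitter on the recorded pulse edges, is
observation noise only: it perturbs the timestamps but not the displaced
volume.

Setting ``flux_exponent=0`` together with a noise-free pump recovers the
ideal quantum sensor (exactly ``round(V / quantum)`` pulses), the analytic
limit used by several unit contracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Nominal sensor calibration, ml of water per flux-sensor pulse.  A fit to
#: the tuning experiments' count/volume ratios, not a manufacturer constant.
DEFAULT_ML_PER_PULSE = 0.135

#: Sensitivity of the pulse quantum to the instantaneous flow
#: (q = q0 * (slot_nom/slot)**gamma).  The recorded count/volume ratios
#: anti-correlate with the event's mean slot (log-log slope -3.7, r=-0.83),
#: but those ratios carry the +-12% printed volume uncertainties, and the
#: certified regression accuracy (~0.5% of the mean volume) upper-bounds the
#: calibration spread that can truly be stochastic; a weak sensitivity
#: consistent with both is adopted.
DEFAULT_FLUX_EXPONENT = 1.2

#: Flux range the sensor is specified to read, L/min.
FLUX_RANGE_L_MIN = (0.1, 3.0)

#: Slot duration (s) at which the sensor delivers exactly ml_per_pulse —
#: the flow at which it was calibrated.
SENSOR_REFERENCE_SLOT_S = 0.0305


class SensorRangeError(ValueError):
    """Raised when a measurement falls outside the flux sensor's range."""


class ProtocolError(RuntimeError):
    """Raised when measurement-cycle commands violate the required order."""


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere from its diameter, V = pi * D**3 / 6.

    Parameters
    ----------
    diameter : float
        Sphere diameter in mm (caliper reading).

    Returns
    -------
    float
        Volume in mm^3.
    """
    if diameter < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter}")
    return math.pi * diameter**3 / 6.0


@dataclass(frozen=True)
class MarbleSpec:
    """A calibration marble with caliper-measured diameter.

    ``volume`` defaults to the analytic sphere volume; if given explicitly
    it must agree with pi*D^3/6 to 1e-9 relative tolerance.
    """

    id: str
    diameter: float                     # mm
    volume: float | None = None         # mm^3
    diameter_uncertainty: float = 0.1   # mm, caliper precision

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"marble diameter must be > 0, got {self.diameter}")
        analytic = sphere_volume(self.diameter)
        if self.volume is None:
            object.__setattr__(self, "volume", analytic)
        elif not math.isclose(self.volume, analytic, rel_tol=1e-9):
            raise ValueError(
                f"volume {self.volume} inconsistent with diameter "
                f"{self.diameter} (analytic {analytic:.6f} mm^3)"
            )


#: The eight tuning marbles.  Diameters are chosen at caliper precision
#: (0.1 mm) so the analytic volumes reproduce the recorded set
#: 8.1, 8.0, 7.3, 7.6, 7.9, 16.1, 23.4, 60.1 ml; the smallest marble
#: (Ma3, D = 24.1 mm) has analytic volume 7329 mm^3 — the certification
#: reference volume.
DEFAULT_MARBLES: tuple[MarbleSpec, ...] = (
    MarbleSpec("Ma1", 24.9),
    MarbleSpec("Ma2", 24.8),
    MarbleSpec("Ma3", 24.1),
    MarbleSpec("Ma4", 24.4),
    MarbleSpec("Ma5", 24.7),
    MarbleSpec("Ma6", 31.3),
    MarbleSpec("Ma7", 35.5),
    MarbleSpec("Ma8", 48.6),
)


@dataclass(frozen=True)
class Formulation:
    """A set of marbles submerged together (data augmentation unit)."""

    id: str
    marble_ids: tuple[str, ...]
    true_volume: float  # mm^3

    def __post_init__(self) -> None:
        if len(self.marble_ids) < 1:
            raise ValueError("a formulation needs at least one marble")
        if self.true_volume <= 0:
            raise ValueError("true_volume must be positive")

    @classmethod
    def from_marbles(cls, fid: str, marbles: Sequence[MarbleSpec]) -> "Formulation":
        if not marbles:
            raise ValueError("a formulation needs at least one marble")
        return cls(
            id=fid,
            marble_ids=tuple(m.id for m in marbles),
            true_volume=float(sum(m.volume for m in marbles)),
        )


@dataclass(frozen=True)
class PumpModel:
    """Stochastic timing model of the pumping stage.

    The smooth (flux-carrying) slot profile of one run is

        steady_run + (start_run - steady_run) * exp(-k / tau) + wander_k,

    where ``steady_run = ts_steady * (1 + steady_rel_std * z)`` and
    ``start_run = ts_start * (1 + start_rel_std * z')`` are drawn once per
    run (z, z' ~ N(0,1) clipped at +-4) — the pump never settles at exactly
    the same rate twice and its starting transient is the most irregular
    part of the record — and ``wander_k`` is a smooth AR(1) flux drift
    (std ``wander_std``, correlation ``wander_corr`` slots) within the run.
    All of these are *real* flow variations: they carry water and therefore
    couple to the flux-dependent sensor quantum.  The *recorded* pulse
    timestamps additionally carry white edge-timing noise
    eps ~ N(0, jitter_std^2) per TTL edge — an observation effect that
    perturbs individual slots (by the difference of two edge errors) but
    telescopes away in slot sums.  Observed slots are clipped to
    [max(ts_steady/10, ts_steady - 5*sigma), ts_start + 5*sigma] with
    sigma the total noise scale.

    Defaults are fitted to the recorded per-event slot statistics of the
    tuning runs (max ~0.037 s, mean 0.0299-0.0315 s, min ~0.026-0.028 s,
    std 0.0007-0.0013 s; between-event mean-slot spread ~1.8%).
    """

    ts_start: float = 0.0373       # s, nominal initial slot
    ts_steady: float = 0.0305      # s, nominal steady-state slot
    tau: float = 3.5               # slots, stabilization constant
    jitter_std: float = 0.00038    # s, edge-timing (observation) noise
    steady_rel_std: float = 0.018  # relative run-to-run steady variation
    start_rel_std: float = 0.03    # relative run-to-run start variation
    wander_std: float = 0.0        # s, smooth within-run flux wander
    wander_corr: float = 15.0      # slots, wander correlation length
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ts_start >= self.ts_steady > 0):
            raise ValueError("require ts_start >= ts_steady > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if min(self.jitter_std, self.steady_rel_std, self.start_rel_std,
               self.wander_std) < 0:
            raise ValueError("noise scales must be >= 0")
        if self.wander_corr <= 0:
            raise ValueError("wander_corr must be > 0")

    @property
    def noise_scale(self) -> float:
        """Total slot noise scale (s), used for the clipping envelope."""
        return (
            2.0 * self.jitter_std
            + self.wander_std
            + max(self.steady_rel_std * self.ts_steady,
                  self.start_rel_std * self.ts_start)
        )

    def quiet(self) -> "PumpModel":
        """Noise-free copy (analytic limit): pure exponential profile."""
        return PumpModel(
            ts_start=self.ts_start, ts_steady=self.ts_steady, tau=self.tau,
            jitter_std=0.0, steady_rel_std=0.0, start_rel_std=0.0,
            wander_std=0.0, wander_corr=self.wander_corr, seed=self.seed,
        )


def _as_rng(rng, fallback_seed: int) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(fallback_seed)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def _clip_slots(pump: PumpModel, slots: np.ndarray) -> np.ndarray:
    sigma = pump.noise_scale
    lo = max(pump.ts_steady / 10.0, pump.ts_steady - 5.0 * sigma)
    hi = pump.ts_start + 5.0 * sigma
    return np.clip(slots, lo, hi)


def _smooth_slot_profile(
    pump: PumpModel, n_slots: int, rng: np.random.Generator
) -> np.ndarray:
    """The flux-carrying slot profile of one run (no timing noise)."""
    steady, start = pump.ts_steady, pump.ts_start
    if pump.steady_rel_std > 0:
        z = float(np.clip(rng.standard_normal(), -4.0, 4.0))
        steady = steady * (1.0 + pump.steady_rel_std * z)
    if pump.start_rel_std > 0:
        z = float(np.clip(rng.standard_normal(), -4.0, 4.0))
        start = start * (1.0 + pump.start_rel_std * z)
    k = np.arange(n_slots, dtype=float)
    profile = steady + (start - steady) * np.exp(-k / pump.tau)
    if pump.wander_std > 0:
        phi = math.exp(-1.0 / pump.wander_corr)
        innov = rng.standard_normal(n_slots) * (
            pump.wander_std * math.sqrt(1.0 - phi * phi)
        )
        wander = np.empty(n_slots)
        acc = rng.standard_normal() * pump.wander_std
        for i in range(n_slots):
            acc = phi * acc + innov[i]
            wander[i] = acc
        profile = profile + wander
    return _clip_slots(pump, profile)


def _observe_slots(
    pump: PumpModel, smooth: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Recorded slots: true slots perturbed by per-edge timing noise."""
    if pump.jitter_std == 0 or smooth.size == 0:
        return smooth
    edges = np.concatenate([[0.0], np.cumsum(smooth)])
    noise = rng.normal(0.0, pump.jitter_std, size=edges.size)
    noise[0] = 0.0
    return _clip_slots(pump, np.diff(edges + noise))


def simulate_slot_sequence(
    pump: PumpModel,
    n_slots: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n_slots`` observed inter-pulse durations from the pump model.

    Observed = smooth flux profile + per-edge timing noise, clipped to the
    pump's noise envelope.  Deterministic given ``pump.seed`` (or an
    explicit ``rng``).
    """
    if n_slots < 1:
        raise ValueError("n_slots must be >= 1")
    rng = _as_rng(rng, pump.seed)
    smooth = _smooth_slot_profile(pump, n_slots, rng)
    return _observe_slots(pump, smooth, rng)


@dataclass(frozen=True)
class PulsePattern:
    """Ordered flux-sensor pulse timestamps for one submersion event."""

    timestamps: np.ndarray            # s, strictly increasing, first at 0
    ml_per_pulse: float = DEFAULT_ML_PER_PULSE

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1 or ts.size < 1:
            raise ValueError("timestamps must be a non-empty 1-D sequence")
        if abs(ts[0]) > 1e-12:
            raise ValueError("first pulse must be at t = 0")
        if self.ml_per_pulse <= 0:
            raise ValueError("ml_per_pulse must be > 0")
        if ts.size > 1:
            slots = np.diff(ts)
            if np.any(slots <= 0):
                raise ValueError("timestamps must be strictly increasing")
            # Implied instantaneous flux must sit in the sensor's range.
            flux_l_min = self.ml_per_pulse / slots * 60.0 / 1000.0
            lo, hi = FLUX_RANGE_L_MIN
            if np.any(flux_l_min < lo) or np.any(flux_l_min > hi):
                raise SensorRangeError(
                    "implied flux outside the sensor range "
                    f"{FLUX_RANGE_L_MIN} L/min: "
                    f"[{flux_l_min.min():.4f}, {flux_l_min.max():.4f}]"
                )

    @property
    def n_pulses(self) -> int:
        return int(self.timestamps.size)

    @property
    def slots(self) -> np.ndarray:
        """Inter-pulse durations, s (the pulse train's first derivative)."""
        return np.diff(self.timestamps)


@dataclass(frozen=True)
class MeasurementEvent:
    """One completed DRAIN-COUNT reading for a formulation.

    ``effective_ml_per_pulse`` is the realized mean water quantum of the
    event (equal to the nominal calibration only for an ideal sensor); the
    pulse count recovers the true volume within one such quantum.
    """

    formulation_id: str
    pattern: PulsePattern
    true_volume: float  # mm^3
    effective_ml_per_pulse: float | None = None

    def __post_init__(self) -> None:
        quantum = (
            self.effective_ml_per_pulse
            if self.effective_ml_per_pulse is not None
            else self.pattern.ml_per_pulse
        )
        expected = self.true_volume / (1000.0 * quantum)
        if abs(self.pattern.n_pulses - expected) > 1.0:
            raise ValueError(
                f"pulse count {self.pattern.n_pulses} inconsistent with "
                f"true volume {self.true_volume} mm^3 "
                f"(expected ~{expected:.2f} pulses at "
                f"{quantum} ml/pulse)"
            )


def measure_object(
    formulation: Formulation,
    pump: PumpModel | None = None,
    ml_per_pulse: float = DEFAULT_ML_PER_PULSE,
    rng: np.random.Generator | int | None = None,
    flux_exponent: float = DEFAULT_FLUX_EXPONENT,
) -> MeasurementEvent:
    """Simulate one submersion measurement of a formulation.

    Water drains along the pump's smooth flux profile; the sensor emits a
    pulse per quantum ``q_k = q0 * (ref_slot / slot_k)**flux_exponent``
    (mm^3, with q0 = 1000*ml_per_pulse and ref_slot the sensor's
    calibration flow) until the displaced volume is
    exhausted, so the pulse count is ``round(V / q0)`` only in the ideal
    limit ``flux_exponent=0``.  Recorded timestamps add white timing
    jitter.
    """
    if pump is None:
        pump = PumpModel()
    if ml_per_pulse <= 0:
        raise ValueError("ml_per_pulse must be > 0")
    rng = _as_rng(rng, pump.seed)
    q0 = 1000.0 * ml_per_pulse  # mm^3 per pulse at nominal flux
    volume = formulation.true_volume

    # Generous upper bound on the pulse count (slow flux shrinks quanta).
    n_upper = int(volume / (q0 * 0.5)) + 80
    smooth = _smooth_slot_profile(pump, n_upper, rng)
    quanta = q0 * (SENSOR_REFERENCE_SLOT_S / smooth) ** flux_exponent
    cum = np.cumsum(quanta)
    if volume < 0.5 * quanta[0]:
        raise SensorRangeError(
            f"volume {volume} mm^3 is below one pulse quantum "
            f"({quanta[0]:.1f} mm^3); sensor cannot register"
        )
    idx = int(np.searchsorted(cum, volume))
    if idx >= cum.size:
        raise SensorRangeError("pulse buffer exhausted; volume too large")
    if idx == 0:
        n_pulses = 1
    else:
        # nearest cumulative displaced volume (rounding behaviour)
        n_pulses = idx if (volume - cum[idx - 1]) < (cum[idx] - volume) else idx + 1

    slots = _observe_slots(pump, smooth[: n_pulses - 1], rng)
    timestamps = np.concatenate([[0.0], np.cumsum(slots)])
    pattern = PulsePattern(timestamps=timestamps, ml_per_pulse=ml_per_pulse)
    effective = float(cum[n_pulses - 1] / n_pulses) / 1000.0
    return MeasurementEvent(
        formulation_id=formulation.id,
        pattern=pattern,
        true_volume=volume,
        effective_ml_per_pulse=effective,
    )


# ---------------------------------------------------------------------------
# Measurement cycle state machine
# ---------------------------------------------------------------------------

#: Cycle states.  EMPTY: sample recipient below the level sensor (NC-LS=0).
#: FULL: filled above the sensor.  ZEROED: drained to the zero level.
#: SUBMERGED: sample in, level above the sensor again.
_STATES = ("EMPTY", "FULL", "ZEROED", "SUBMERGED")


class MeasurementCycle:
    """State machine enforcing FILL -> ZERO -> SUBMERGE -> DRAIN-COUNT.

    Pulse counting is active only during the DRAIN-COUNT phase; commands out
    of order raise :class:`ProtocolError`.  ``drain`` with the water already
    at zero ([NC-LS] = 0) is a no-op, mirroring the hardware.
    """

    def __init__(
        self,
        pump: PumpModel | None = None,
        ml_per_pulse: float = DEFAULT_ML_PER_PULSE,
        seed: int | None = None,
        flux_exponent: float = DEFAULT_FLUX_EXPONENT,
    ) -> None:
        self.pump = pump if pump is not None else PumpModel()
        self.ml_per_pulse = ml_per_pulse
        self.flux_exponent = flux_exponent
        self._rng = np.random.default_rng(
            self.pump.seed if seed is None else seed
        )
        self.state = "EMPTY"
        self._sample: Formulation | None = None
        self.log: list[MeasurementEvent] = []

    def process(self, command) -> None:
        name, *args = command if isinstance(command, (tuple, list)) else (command,)
        name = str(name).lower()
        if name == "fill":
            if self.state != "EMPTY":
                raise ProtocolError(f"fill issued in state {self.state}")
            self.state = "FULL"
        elif name == "zero":
            if self.state != "FULL":
                raise ProtocolError(f"zero issued in state {self.state}")
            self.state = "ZEROED"
        elif name == "submerge":
            if self.state != "ZEROED":
                raise ProtocolError(
                    f"submerge issued in state {self.state}; the recipient "
                    "must be zeroed first"
                )
            if not args or not isinstance(args[0], Formulation):
                raise ProtocolError("submerge requires a Formulation argument")
            self._sample = args[0]
            self.state = "SUBMERGED"
        elif name == "drain":
            if self.state in ("EMPTY", "ZEROED"):
                return  # water already at zero: nothing to count
            if self.state != "SUBMERGED":
                raise ProtocolError(f"drain issued in state {self.state}")
            event = measure_object(
                self._sample, self.pump, self.ml_per_pulse,
                rng=self._rng, flux_exponent=self.flux_exponent,
            )
            self.log.append(event)
            self._sample = None
            self.state = "ZEROED"
        else:
            raise ProtocolError(f"unknown command {command!r}")

    def run(self, commands: Iterable) -> list[MeasurementEvent]:
        for command in commands:
            self.process(command)
        return self.log


def run_measurement_cycle(
    commands: Iterable,
    pump: PumpModel | None = None,
    ml_per_pulse: float = DEFAULT_ML_PER_PULSE,
    seed: int | None = None,
    flux_exponent: float = DEFAULT_FLUX_EXPONENT,
) -> list[MeasurementEvent]:
    """Run a command stream through a fresh cycle and return its event log."""
    cycle = MeasurementCycle(pump, ml_per_pulse, seed=seed,
                             flux_exponent=flux_exponent)
    return cycle.run(commands)


# ---------------------------------------------------------------------------
# Formulation sets and batch simulation
# ---------------------------------------------------------------------------

def generate_formulation_set(
    marbles: Sequence[MarbleSpec] = DEFAULT_MARBLES,
    n_formulations: int = 44,
    seed: int | None = None,
    include_singletons: bool = True,
    max_size: int = 4,
    max_volume: float | None = None,
) -> list[Formulation]:
    """Random multi-marble formulations mirroring the tuning protocol.

    The base measurements are the single marbles; augmentation submerges
    random subsets of 2..max_size marbles together.  With
    ``include_singletons`` the first ``min(len(marbles), n_formulations)``
    formulations are the singletons, so the set spans the single marbles'
    volume range.  Combined volumes are kept within ``max_volume`` (mm^3;
    by default the largest single marble), i.e. augmentation stays inside
    the span the sensor was calibrated on.
    """
    marbles = list(marbles)
    if not marbles:
        raise ValueError("marble list must not be empty")
    if n_formulations < 1:
        raise ValueError("n_formulations must be >= 1")
    if max_volume is None:
        max_volume = max(m.volume for m in marbles) + 1.0
    if max_volume < min(m.volume for m in marbles):
        raise ValueError("max_volume excludes every single marble")
    rng = np.random.default_rng(seed)
    forms: list[Formulation] = []
    if include_singletons:
        for m in marbles[: n_formulations]:
            if m.volume <= max_volume:
                forms.append(
                    Formulation.from_marbles(f"F{len(forms) + 1:02d}", [m])
                )
    hi = min(max_size, len(marbles))
    while len(forms) < n_formulations:
        size = int(rng.integers(2, hi + 1)) if hi >= 2 else 1
        idx = rng.choice(len(marbles), size=size, replace=False)
        members = [marbles[i] for i in sorted(idx)]
        if sum(m.volume for m in members) > max_volume:
            continue  # resample: outside the calibrated span
        forms.append(Formulation.from_marbles(f"F{len(forms) + 1:02d}", members))
    return forms


def simulate_measurements(
    formulations: Sequence[Formulation],
    pump: PumpModel | None = None,
    ml_per_pulse: float = DEFAULT_ML_PER_PULSE,
    seed: int | None = None,
    flux_exponent: float = DEFAULT_FLUX_EXPONENT,
) -> list[MeasurementEvent]:
    """Measure every formulation once; deterministic given ``seed``."""
    if pump is None:
        pump = PumpModel()
    rng = np.random.default_rng(pump.seed if seed is None else seed)
    return [
        measure_object(f, pump, ml_per_pulse, rng=rng,
                       flux_exponent=flux_exponent)
        for f in formulations
    ]


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def events_to_frames(
    events: Sequence[MeasurementEvent],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long pulse table (event_id, pulse_index, timestamp_s) + event table."""
    pulses = pd.DataFrame(
        [
            (e.formulation_id, i, t)
            for e in events
            for i, t in enumerate(e.pattern.timestamps)
        ],
        columns=["event_id", "pulse_index", "timestamp_s"],
    )
    meta = pd.DataFrame(
        {
            "event_id": [e.formulation_id for e in events],
            "true_volume_mm3": [e.true_volume for e in events],
            "ml_per_pulse": [e.pattern.ml_per_pulse for e in events],
            "effective_ml_per_pulse": [
                e.effective_ml_per_pulse for e in events
            ],
        }
    )
    return pulses, meta


def write_events_csv(events: Sequence[MeasurementEvent], out_dir) -> None:
    """Write ``pulses.csv`` and ``events.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pulses, meta = events_to_frames(events)
    pulses.to_csv(out / "pulses.csv", index=False)
    meta.to_csv(out / "events.csv", index=False)


def read_events_csv(in_dir) -> list[MeasurementEvent]:
    """Rebuild measurement events from ``pulses.csv`` / ``events.csv``."""
    src = Path(in_dir)
    pulses = pd.read_csv(src / "pulses.csv")
    meta = pd.read_csv(src / "events.csv").set_index("event_id")
    events = []
    for eid, grp in pulses.groupby("event_id", sort=False):
        ts = grp.sort_values("pulse_index")["timestamp_s"].to_numpy()
        row = meta.loc[eid]
        pattern = PulsePattern(ts, ml_per_pulse=float(row["ml_per_pulse"]))
        eff = row.get("effective_ml_per_pulse")
        events.append(
            MeasurementEvent(
                str(eid), pattern, float(row["true_volume_mm3"]),
                effective_ml_per_pulse=None if pd.isna(eff) else float(eff),
            )
        )
    return events


def write_formulations_csv(forms: Sequence[Formulation], path) -> None:
    pd.DataFrame(
        {
            "formulation_id": [f.id for f in forms],
            "marble_ids": ["+".join(f.marble_ids) for f in forms],
            "true_volume_mm3": [f.true_volume for f in forms],
        }
    ).to_csv(path, index=False)


__all__ = [
    "DEFAULT_ML_PER_PULSE", "DEFAULT_FLUX_EXPONENT", "FLUX_RANGE_L_MIN",
    "SENSOR_REFERENCE_SLOT_S",
    "DEFAULT_MARBLES", "SensorRangeError", "ProtocolError", "sphere_volume",
    "MarbleSpec", "Formulation", "PumpModel", "PulsePattern",
    "MeasurementEvent", "simulate_slot_sequence", "measure_object",
    "MeasurementCycle", "run_measurement_cycle", "generate_formulation_set",
    "simulate_measurements", "events_to_frames", "write_events_csv",
    "read_events_csv", "write_formulations_csv",
]
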