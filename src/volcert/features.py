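"""Pulse-pattern feature extraction and supervised dataset assembly.

Each submersion event is summarized by 23 scalars, in this fixed order:

* ``PuC``  — pulse count;
* ``TS1..TS20`` — the first 20 time slots (inter-pulse durations, s).
  Patterns longer than 21 pulses are truncated, never padded: the highest
  timing variability lives in the pump's irregular start, so the first
  slots carry the discriminative dynamics;
* ``Twd`` — total water-displacement time, s (last minus first pulse);
* ``A0f`` — amplitude of the Fourier DC component of the 50%-duty-cycle
  square waveform reconstructed from the pulse timestamps on a fixed
  1 kHz grid.

The supervised dataset pairs the feature matrix X (n x 23) with the
analytic (caliper) volumes Y in mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .device import MeasurementEvent, PulsePattern

#: Number of leading time slots kept as features.
N_SLOTS = 20

#: Column order of the flattened feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    ("puc",) + tuple(f"ts{i:02d}" for i in range(1, N_SLOTS + 1)) + ("twd", "a0f")
)

#: Sampling rate of the reconstructed square waveform, Hz.  At least 25x
#: faster than the shortest observed slot (~0.026 s), so the DC estimate is
#: sampling-rate independent up to discretization.
SQUARE_WAVE_SAMPLE_HZ = 1000.0


class ShortPatternError(ValueError):
    """Pattern has fewer than 21 pulses and cannot fill 20 time slots."""


@dataclass(frozen=True)
class FeatureVector:
    """The 23 features of one measurement event."""

    puc: int
    ts: np.ndarray   # first 20 slots, s
    twd: float       # s
    a0f: float       # dimensionless DC amplitude

    def __post_init__(self) -> None:
        ts = np.asarray(self.ts, dtype=float)
        object.__setattr__(self, "ts", ts)
        if ts.shape != (N_SLOTS,):
            raise ValueError(f"ts must have exactly {N_SLOTS} entries")
        if np.any(ts <= 0):
            raise ValueError("all time slots must be positive")
        if self.twd + 1e-12 < ts.sum():
            raise ValueError("twd cannot be smaller than the sum of its slots")

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 23-vector [puc, ts1..ts20, twd, a0f]."""
        return np.concatenate([[float(self.puc)], self.ts, [self.twd, self.a0f]])


def square_wave_dc(
    timestamps: np.ndarray, sample_hz: float = SQUARE_WAVE_SAMPLE_HZ
) -> float:
    """DC (zero-frequency Fourier) amplitude of the reconstructed waveform.

    The flux sensor emits a square wave of constant 50% duty cycle and
    variable frequency; between pulses k and k+1 the line is high for the
    first half of the slot.  The DC term of the DFT is the sample mean, so a
    perfect half-duty square wave yields 0.5 regardless of frequency.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size < 2:
        raise ValueError("need at least two pulses to reconstruct a waveform")
    duration = ts[-1] - ts[0]
    n = max(1, int(round(duration * sample_hz)))
    grid = ts[0] + (np.arange(n) + 0.5) / sample_hz  # midpoint sampling
    idx = np.clip(np.searchsorted(ts, grid, side="right") - 1, 0, ts.size - 2)
    frac = grid - ts[idx]
    half = (ts[idx + 1] - ts[idx]) / 2.0
    return float((frac < half).mean())


def extract_features(pattern: PulsePattern) -> FeatureVector:
    """Convert a pulse pattern into its 23-feature vector.

    Raises :class:`ShortPatternError` for patterns with fewer than 21
    pulses — short events are rejected, never padded.
    """
    n = pattern.n_pulses
    if n < N_SLOTS + 1:
        raise ShortPatternError(
            f"pattern has {n} pulses; {N_SLOTS + 1} are required to "
            f"yield {N_SLOTS} time slots (padding is not applied)"
        )
    slots = pattern.slots
    return FeatureVector(
        puc=n,
        ts=slots[:N_SLOTS].copy(),
        twd=float(pattern.timestamps[-1] - pattern.timestamps[0]),
        a0f=square_wave_dc(pattern.timestamps),
    )


@dataclass(frozen=True)
class Dataset:
    """Feature matrix X (n x 23), target volumes Y (mm^3) and event ids."""

    X: np.ndarray
    y: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float).reshape(-1, len(FEATURE_NAMES))
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if X.shape[0] != y.size or y.size != len(self.ids):
            raise ValueError("X rows, y length and ids length must agree")
        if X.size and not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if y.size and (not np.all(np.isfinite(y)) or np.any(y <= 0)):
            raise ValueError("all target volumes must be finite and positive")

    @property
    def n(self) -> int:
        return int(self.y.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df["volume_mm3"] = self.y
        df.insert(0, "event_id", list(self.ids))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        missing = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing or "volume_mm3" not in df.columns:
            raise ValueError(
                "expected columns puc, ts01..ts20, twd, a0f, volume_mm3; "
                f"missing {missing + (['volume_mm3'] if 'volume_mm3' not in df.columns else [])}"
            )
        ids = (
            df["event_id"].astype(str).tolist()
            if "event_id" in df.columns
            else [str(i) for i in range(len(df))]
        )
        return cls(
            X=df[list(FEATURE_NAMES)].to_numpy(float),
            y=df["volume_mm3"].to_numpy(float),
            ids=tuple(ids),
        )

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))


def build_dataset(events: list[MeasurementEvent]) -> Dataset:
    """Stack per-event feature vectors into a supervised dataset.

    Events whose patterns are too short to featurize are rejected and
    reported through a warning naming the offending event ids; they are
    never silently dropped.
    """
    rows, vols, ids, rejected = [], [], [], []
    for event in events:
        try:
            fv = extract_features(event.pattern)
        except ShortPatternError:
            rejected.append(event.formulation_id)
            continue
        rows.append(fv.to_array())
        vols.append(event.true_volume)
        ids.append(event.formulation_id)
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} event(s) with fewer than "
            f"{N_SLOTS + 1} pulses: {rejected}",
            UserWarning,
            stacklevel=2,
        )
    X = np.asarray(rows, float).reshape(-1, len(FEATURE_NAMES))
    return Dataset(X=X, y=np.asarray(vols, float), ids=tuple(ids))


def load_external_dataset(path, y_path=None) -> Dataset:
    """Load a plain numeric table of 23 feature columns (+1 volume column).

    Accepts either a single table with 24 columns (features then volume) or
    a 23-column feature table plus a separate single-column volume file.
    Header rows are optional; column meaning is positional.
    """
    X = _read_numeric_table(path)
    if y_path is not None:
        if X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature table must have {len(FEATURE_NAMES)} columns, "
                f"got {X.shape[1]} (expected layout: 23 features + separate Y)"
            )
        y = _read_numeric_table(y_path).ravel()
    else:
        if X.shape[1] != len(FEATURE_NAMES) + 1:
            raise ValueError(
                f"table must have {len(FEATURE_NAMES) + 1} columns "
                f"(23 features + 1 volume), got {X.shape[1]}"
            )
        X, y = X[:, :-1], X[:, -1]
    ids = tuple(str(i) for i in range(X.shape[0]))
    return Dataset(X=X, y=y, ids=ids)


def _read_numeric_table(path) -> np.ndarray:
    df = pd.read_csv(Path(path), header=None)
    # Tolerate a header row of column names.
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:]
    return df.apply(pd.to_numeric).to_numpy(float)


__all__ = [
    "N_SLOTS", "FEATURE_NAMES", "SQUARE_WAVE_SAMPLE_HZ", "ShortPatternError",
    "FeatureVector", "Dataset", "square_wave_dc", "extract_features",
    "build_dataset", "load_external_dataset",
]
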