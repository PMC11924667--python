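"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* fNIRS arrays are ``(n_channels, 2, n_times)``: axis 1 is the wavelength
  pair (760, 850 nm) for raw intensity / optical density, or the chromophore
  pair (HbO, HbR) for concentration series.
* Concentration changes are expressed in micromolar (uM).
* The channel table is a :class:`pandas.DataFrame` with columns
  ``name, source, detector, separation_mm, is_short, roi`` and one row per
  channel, aligned with axis 0 of the data arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError

CHROMA = ("hbo", "hbr")
CHANNEL_COLUMNS = ("name", "source", "detector", "separation_mm", "is_short", "roi")

#: canonical physiology signal names, fixed order
PHYSIO_SIGNALS = ("heart_rate", "respiration", "spo2", "ppg", "gsr", "temperature")

#: units used in the physiology CSV schema
PHYSIO_CSV_COLUMNS = {
    "heart_rate": "heart_rate_bpm",
    "respiration": "respiration_brpm",
    "spo2": "spo2_pct",
    "ppg": "ppg_au",
    "gsr": "gsr_us",
    "temperature": "temperature_c",
}

CONDITIONS = ("speech", "control")


def _check_channel_table(table: pd.DataFrame, n_channels: int) -> None:
    missing = set(CHANNEL_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"channel table missing columns: {sorted(missing)}")
    if len(table) != n_channels:
        raise InvalidInputError(
            f"channel table has {len(table)} rows for {n_channels} channels"
        )


@dataclass
class RawScan:
    """Dual-wavelength raw intensity time series plus montage metadata."""

    intensity: np.ndarray  # (n_channels, 2, n_times), arbitrary units, > 0
    sample_rate: float  # Hz
    wavelengths: tuple[float, float]  # nm
    channel_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise InvalidInputError(
                "intensity must be (n_channels, 2 wavelengths, n_times)"
            )
        if len(self.wavelengths) != 2:
            raise InvalidInputError("exactly two wavelengths required")
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        _check_channel_table(self.channel_table, self.intensity.shape[0])

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sample_rate

    def select(self, mask: np.ndarray) -> "RawScan":
        """Return a scan restricted to the channels where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return RawScan(
            intensity=self.intensity[mask],
            sample_rate=self.sample_rate,
            wavelengths=self.wavelengths,
            channel_table=self.channel_table.loc[mask].reset_index(drop=True),
        )


@dataclass
class HemoTimeSeries:
    """HbO/HbR concentration change series (uM) per channel."""

    concentration: np.ndarray  # (n_channels, 2 chroma, n_times)
    sample_rate: float
    channel_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 3 or self.concentration.shape[1] != 2:
            raise InvalidInputError(
                "concentration must be (n_channels, 2 chroma, n_times)"
            )
        if not np.all(np.isfinite(self.concentration)):
            raise InvalidInputError("concentration contains non-finite values")
        _check_channel_table(self.channel_table, self.concentration.shape[0])

    @property
    def n_channels(self) -> int:
        return self.concentration.shape[0]

    @property
    def n_times(self) -> int:
        return self.concentration.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sample_rate

    def select(self, mask: np.ndarray) -> "HemoTimeSeries":
        mask = np.asarray(mask, dtype=bool)
        return HemoTimeSeries(
            concentration=self.concentration[mask],
            sample_rate=self.sample_rate,
            channel_table=self.channel_table.loc[mask].reset_index(drop=True),
        )

    def copy(self) -> "HemoTimeSeries":
        return replace(self, concentration=self.concentration.copy())

    @property
    def long_mask(self) -> np.ndarray:
        return ~self.channel_table["is_short"].to_numpy(dtype=bool)

    @property
    def short_mask(self) -> np.ndarray:
        return self.channel_table["is_short"].to_numpy(dtype=bool)


@dataclass
class EventSchedule:
    """Stimulus onsets/durations/conditions for one session."""

    onset: np.ndarray  # s
    duration: np.ndarray  # s
    condition: np.ndarray  # str, in CONDITIONS

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.duration = np.asarray(self.duration, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if not (len(self.onset) == len(self.duration) == len(self.condition)):
            raise InvalidInputError("onset/duration/condition lengths differ")
        if np.any(np.diff(self.onset) <= 0):
            raise InvalidInputError("onsets must be strictly increasing")
        if np.any(self.duration <= 0):
            raise InvalidInputError("durations must be positive")
        unknown = set(self.condition) - set(CONDITIONS)
        if unknown:
            raise InvalidInputError(f"unknown conditions: {sorted(unknown)}")

    @property
    def n_events(self) -> int:
        return len(self.onset)

    def onsets_for(self, condition: str) -> np.ndarray:
        return self.onset[self.condition == condition]

    def durations_for(self, condition: str) -> np.ndarray:
        return self.duration[self.condition == condition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset": self.onset, "duration": self.duration, "trial_type": self.condition}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventSchedule":
        return cls(
            onset=frame["onset"].to_numpy(dtype=float),
            duration=frame["duration"].to_numpy(dtype=float),
            condition=frame["trial_type"].to_numpy(dtype=object),
        )


@dataclass
class PhysioRecord:
    """Six peripheral physiology time series at a common native rate."""

    signals: dict[str, np.ndarray]
    sample_rate: float  # Hz, native (500 Hz for the WINGS module)
    #: sessions may flag a signal as unusable (e.g. a loose respiration belt)
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if set(self.signals) != set(PHYSIO_SIGNALS):
            raise InvalidInputError(
                f"physiology record must contain exactly {PHYSIO_SIGNALS}"
            )
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise InvalidInputError("physiology signals must share one length")
        for name, values in self.signals.items():
            arr = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"non-finite values in physiology signal {name}")
            self.signals[name] = arr
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")

    @property
    def n_times(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration(self) -> float:
        return self.n_times / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sample_rate
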