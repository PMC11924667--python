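"""Epoch extraction and condition-wise block averaging.

The same epoching engine serves hemodynamic series and peripheral
physiology; physiology is simply not band-pass filtered beforehand.
Baseline correction subtracts the mean of the pre-onset interval, and the
95% confidence band is the normal approximation (1.96 x SEM across
epochs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EventSchedule
from .errors import NoEpochsError


@dataclass
class EvokedResponse:
    """Condition-wise mean waveforms with confidence bands."""

    epoch_times: np.ndarray  # s, relative to onset
    mean: dict[str, np.ndarray]  # condition -> (..., n_epoch_samples)
    ci95: dict[str, np.ndarray]  # 1.96 * SEM, same shapes
    n_epochs: dict[str, int]
    n_dropped: dict[str, int]  # epochs overlapping a recording edge
    window: tuple[float, float]


def extract_epochs(
    data: np.ndarray,
    sample_rate: float,
    onsets: np.ndarray,
    window: tuple[float, float] = (-1.0, 15.0),
) -> tuple[np.ndarray, int]:
    """Stack per-onset epochs along a new leading axis.

    ``data`` has time on its last axis.  Epochs that do not fit inside the
    recording are dropped and counted.  Each epoch is baseline-corrected
    by the mean of its pre-onset samples.
    """
    n_times = data.shape[-1]
    w0, w1 = window
    n_pre = int(round(-w0 * sample_rate))
    n_post = int(round(w1 * sample_rate))
    epochs = []
    dropped = 0
    for onset in np.asarray(onsets, dtype=float):
        i_on = int(round(onset * sample_rate))
        start, stop = i_on - n_pre, i_on + n_post + 1
        if start < 0 or stop > n_times:
            dropped += 1
            continue
        epoch = np.array(data[..., start:stop], dtype=float)
        if n_pre > 0:
            epoch = epoch - epoch[..., :n_pre].mean(axis=-1, keepdims=True)
        epochs.append(epoch)
    if not epochs:
        return np.empty((0,) + data.shape[:-1] + (n_pre + n_post + 1,)), dropped
    return np.stack(epochs), dropped


def extract_epochs_and_average(
    data: np.ndarray,
    sample_rate: float,
    schedule: EventSchedule,
    window: tuple[float, float] = (-1.0, 15.0),
) -> EvokedResponse:
    """Condition-wise epoch means with 95% confidence half-widths."""
    w0, w1 = window
    n_pre = int(round(-w0 * sample_rate))
    n_post = int(round(w1 * sample_rate))
    epoch_times = (np.arange(n_pre + n_post + 1) - n_pre) / sample_rate

    mean: dict[str, np.ndarray] = {}
    ci95: dict[str, np.ndarray] = {}
    n_epochs: dict[str, int] = {}
    n_dropped: dict[str, int] = {}
    for condition in np.unique(schedule.condition):
        epochs, dropped = extract_epochs(
            data, sample_rate, schedule.onsets_for(condition), window
        )
        if epochs.shape[0] == 0:
            raise NoEpochsError(f"no usable epochs for condition {condition!r}")
        n = epochs.shape[0]
        mean[condition] = epochs.mean(axis=0)
        sem = epochs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(
            mean[condition]
        )
        ci95[condition] = 1.96 * sem
        n_epochs[condition] = n
        n_dropped[condition] = dropped
    return EvokedResponse(
        epoch_times=epoch_times,
        mean=mean,
        ci95=ci95,
        n_epochs=n_epochs,
        n_dropped=n_dropped,
        window=window,
    )


def pooled_average(
    sessions: list[tuple[np.ndarray, float, EventSchedule]],
    window: tuple[float, float] = (-1.0, 15.0),
) -> EvokedResponse:
    """Pool epochs from several sessions before averaging.

    Each entry is ``(data, sample_rate, schedule)``; all sessions must
    share the sample rate and data shape.  Pooling across sessions (rather
    than averaging session means) weights every trial equally.
    """
    rates = {rate for _, rate, _ in sessions}
    if len(rates) != 1:
        raise ValueError("sessions must share one sample rate")
    rate = rates.pop()
    conditions = sorted(
        {c for _, _, schedule in sessions for c in np.unique(schedule.condition)}
    )
    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    epoch_times = (np.arange(n_pre + n_post + 1) - n_pre) / rate

    mean, ci95, n_epochs, n_dropped = {}, {}, {}, {}
    for condition in conditions:
        stacks, dropped = [], 0
        for data, _, schedule in sessions:
            epochs, d = extract_epochs(data, rate, schedule.onsets_for(condition), window)
            dropped += d
            if epochs.shape[0]:
                stacks.append(epochs)
        if not stacks:
            raise NoEpochsError(f"no usable epochs for condition {condition!r}")
        pooled = np.concatenate(stacks, axis=0)
        n = pooled.shape[0]
        mean[condition] = pooled.mean(axis=0)
        sem = pooled.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(
            mean[condition]
        )
        ci95[condition] = 1.96 * sem
        n_epochs[condition] = n
        n_dropped[condition] = dropped
    return EvokedResponse(
        epoch_times=epoch_times,
        mean=mean,
        ci95=ci95,
        n_epochs=n_epochs,
        n_dropped=n_dropped,
        window=window,
    )


def compute_prq(heart_rate: np.ndarray, respiration: np.ndarray) -> np.ndarray:
    """Pulse-respiration quotient: heart rate / respiration rate.

    Zero respiration samples yield masked (NaN) outputs with a warning.
    """
    hr = np.asarray(heart_rate, dtype=float)
    rr = np.asarray(respiration, dtype=float)
    if hr.shape != rr.shape:
        raise ValueError("heart rate and respiration must be aligned")
    out = np.full_like(hr, np.nan)
    ok = rr != 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero respiration samples masked in PRQ",
            stacklevel=2,
        )
    out[ok] = hr[ok] / rr[ok]
    return out
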