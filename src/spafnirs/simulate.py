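"""Synthetic multi-session SPA-fNIRS data generator with known ground truth.

Emulates the study conditions of a single-subject auditory block design:
a ~20 min session containing 20 speech trials (fixed stimulus set, 5.18 to
7.31 s, mean 6.1 s) and 20 silence trials (6 s), separated by 15 to 30 s
inter-stimulus intervals.  Long channels carry an HRF-shaped evoked
response (auditory ROIs only), a superficial hemodynamic component shared
with the short channels, six peripheral physiology signals coupled in at
known signal-specific lags, and white noise.  Short channels carry only
the superficial component and noise, so they contain zero evoked energy
by construction.

All randomness is driven by ``config.seed``; the same seed reproduces the
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .containers import CONDITIONS, PHYSIO_SIGNALS, EventSchedule, PhysioRecord, RawScan
from .errors import InvalidInputError, ScheduleInfeasibleError
from .hrf import HrfParams, stimulus_regressor
from .preprocess import forward_mbll

ROIS = (
    "left_primary_auditory",
    "right_primary_auditory",
    "left_secondary_auditory",
    "right_secondary_auditory",
    "left_ifg",
    "right_ifg",
)
ACTIVE_ROIS = ROIS[:4]

#: (gain uM per z-unit, lag s) per physiology signal; lags follow the mean
#: optimal transit times reported for this paradigm.
DEFAULT_COUPLINGS = {
    "heart_rate": (0.25, 5.50),
    "respiration": (0.20, 28.17),
    "spo2": (0.15, 18.83),
    "ppg": (0.20, 0.67),
    "gsr": (0.20, 20.83),
    "temperature": (0.10, 10.00),
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated multi-session experiment."""

    n_sessions: int = 10
    n_long_channels: int = 38
    n_short_channels: int = 8
    sample_rate_raw: float = 5.1  # Hz, fNIRS native
    physio_sample_rate: float = 500.0  # Hz, physiology native
    session_duration: float = 1200.0  # s
    n_trials_per_condition: int = 20
    stim_duration_range: tuple[float, float] = (5.18, 7.31)
    stim_duration_mean: float = 6.1
    control_duration: float = 6.0
    isi_range: tuple[float, float] = (15.0, 30.0)
    hrf_params: HrfParams = field(default_factory=HrfParams)
    boxcar_width: float = 3.0
    rois: tuple[str, ...] = ROIS
    active_rois: tuple[str, ...] = ACTIVE_ROIS
    speech_amplitude: float = 1.0  # uM, HbO evoked amplitude in active ROIs
    control_amplitude: float = 0.0
    hbr_ratio: float = -1.0 / 3.0  # evoked HbR = ratio * HbO
    session_beta_sd: float = 0.3  # uM, session-level shared amplitude jitter
    roi_beta_sd: float = 0.1  # uM, per-ROI jitter within a session
    physio_couplings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS)
    )
    superficial_gain: float = 1.0  # multiplies per-channel superficial gains
    superficial_sd: float = 2.0  # uM, HbO sd of the shared scalp component
    superficial_band: tuple[float, float] = (0.01, 0.5)  # Hz
    noise_sd: float = 0.3  # uM, white measurement noise
    long_separation_mm: float = 30.0
    short_separation_mm: float = 8.0
    ppf: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.stim_duration_range
        if not (5.18 - 1e-9 <= lo < hi <= 7.31 + 1e-9):
            raise InvalidInputError("stim_duration_range must lie within [5.18, 7.31] s")
        ilo, ihi = self.isi_range
        if not (15.0 - 1e-9 <= ilo < ihi <= 30.0 + 1e-9):
            raise InvalidInputError("isi_range must lie within [15, 30] s")
        if not (lo <= self.stim_duration_mean <= hi):
            raise InvalidInputError("stim_duration_mean outside stim_duration_range")
        for name, (gain, lag) in self.physio_couplings.items():
            if name not in PHYSIO_SIGNALS:
                raise InvalidInputError(f"unknown physiology signal {name!r}")
            if not np.isfinite(gain):
                raise InvalidInputError(f"non-finite gain for {name}")
            if not 0.0 <= lag <= 30.0:
                raise InvalidInputError(f"coupling lag for {name} outside [0, 30] s")
        if self.n_sessions < 1 or self.n_long_channels < 1:
            raise InvalidInputError("need at least one session and one long channel")
        if set(self.active_rois) - set(self.rois):
            raise InvalidInputError("active_rois must be a subset of rois")


@dataclass
class GroundTruth:
    """Injected signal parameters for one session."""

    channel_betas: np.ndarray  # (n_channels, 2 chroma, 2 conditions), uM
    roi_amplitudes: dict[str, float]  # realized HbO speech amplitude per ROI
    lags: dict[str, float]  # injected physiology lag, s
    superficial: np.ndarray  # (2 chroma, n_times_raw), uM, unit-gain component
    superficial_gains: np.ndarray  # per-channel gain applied to `superficial`
    channel_table: pd.DataFrame


@dataclass
class SessionBundle:
    session_index: int
    raw: RawScan
    physio: PhysioRecord
    schedule: EventSchedule
    truth: GroundTruth


def fixed_trial_durations(
    n: int, lo: float, hi: float, mean: float
) -> np.ndarray:
    """Deterministic stimulus duration set spanning (lo, hi) with exact mean.

    The study's speech stimuli are a fixed list of concatenated-sentence
    trials, so durations are a fixed set (permuted per session), not fresh
    random draws.  The set is built from beta-distribution quantiles whose
    mean matches the requested mean, then nudged onto it exactly.
    """
    if n == 1:
        return np.array([mean])
    m = (mean - lo) / (hi - lo)
    a = 2.0
    b = a * (1.0 - m) / m
    from scipy.stats import beta as beta_dist

    q = beta_dist.ppf((np.arange(n) + 0.5) / n, a, b)
    d = lo + (hi - lo) * q
    for _ in range(100):
        d = np.clip(d + (mean - d.mean()), lo, hi)
        if abs(d.mean() - mean) < 1e-12:
            break
    return d


def _draw_schedule(config: SimulationConfig, rng: np.random.Generator) -> EventSchedule:
    n = config.n_trials_per_condition
    speech_durations = rng.permutation(
        fixed_trial_durations(
            n, *config.stim_duration_range, config.stim_duration_mean
        )
    )
    durations = np.empty(2 * n)
    conditions = np.array(
        ["speech"] * n + ["control"] * n, dtype=object
    )[rng.permutation(2 * n)]
    durations[conditions == "speech"] = speech_durations
    durations[conditions == "control"] = config.control_duration

    ilo, ihi = config.isi_range
    tail = 15.0  # last epoch must fit (-1, +15) s window
    # infeasible even at the minimum ISI?
    min_last_onset = 2 * n * ilo + durations[:-1].sum()
    if min_last_onset + tail > config.session_duration:
        raise ScheduleInfeasibleError(
            f"cannot place {2 * n} trials with ISI >= {ilo} s in "
            f"{config.session_duration} s"
        )
    for _ in range(200):
        isis = rng.uniform(ilo, ihi, 2 * n)
        onsets = np.cumsum(isis) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
        if onsets[-1] + tail <= config.session_duration:
            return EventSchedule(onset=onsets, duration=durations, condition=conditions)
    # deterministic fallback: shrink the drawn ISIs toward the minimum
    slack = config.session_duration - tail - durations[:-1].sum() - 2 * n * ilo
    alpha = min(1.0, slack / max(1e-12, (isis - ilo).sum()))
    isis = ilo + alpha * (isis - ilo)
    onsets = np.cumsum(isis) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    return EventSchedule(onset=onsets, duration=durations, condition=conditions)


def _slow_noise(
    rng: np.random.Generator, times: np.ndarray, cutoff_hz: float
) -> np.ndarray:
    """Unit-variance low-frequency noise evaluated on ``times``."""
    r0 = 2.0  # Hz, generation rate for the latent walk
    n0 = int(np.ceil(times[-1] * r0)) + 8
    white = rng.standard_normal(n0)
    sigma = r0 / (2.0 * np.pi * cutoff_hz)
    smooth = gaussian_filter1d(white, sigma, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    t0 = np.arange(n0) / r0
    return np.interp(times, t0, smooth)


def _gsr_bump_kernel(sample_rate: float) -> np.ndarray:
    """Stimulus-locked electrodermal rise: delayed gamma-shaped bump."""
    t = np.arange(0.0, 12.0, 1.0 / sample_rate)
    return gamma_dist.pdf(t - 2.0, 2.0, scale=1.5)


def generate_physio(
    config: SimulationConfig,
    schedule: EventSchedule,
    rng: np.random.Generator,
) -> PhysioRecord:
    """Six peripheral physiology signals at the native physiology rate."""
    fs = config.physio_sample_rate
    n = int(round(config.session_duration * fs))
    t = np.arange(n) / fs

    respiration = 15.0 + 1.5 * _slow_noise(rng, t, 0.01)
    resp_hz = respiration / 60.0
    heart_rate = (
        62.0
        + 3.0 * _slow_noise(rng, t, 0.02)
        + 1.5 * np.sin(2.0 * np.pi * np.cumsum(resp_hz) / fs)
    )
    spo2 = np.clip(98.0 + 0.4 * _slow_noise(rng, t, 0.005), 94.0, 100.0)
    cardiac_phase = 2.0 * np.pi * np.cumsum(heart_rate / 60.0) / fs
    ppg = (1.0 + 0.3 * _slow_noise(rng, t, 0.02)) * np.sin(cardiac_phase)
    gsr = 2.0 + 0.5 * _slow_noise(rng, t, 0.01)
    kernel = _gsr_bump_kernel(fs)
    for onset in schedule.onsets_for("speech"):
        i0 = int(round(onset * fs))
        seg = gsr[i0 : i0 + len(kernel)]
        seg += 0.3 * kernel[: len(seg)]
    temperature = 33.0 + 0.3 * _slow_noise(rng, t, 0.002)

    return PhysioRecord(
        signals={
            "heart_rate": heart_rate,
            "respiration": respiration,
            "spo2": spo2,
            "ppg": ppg,
            "gsr": gsr,
            "temperature": temperature,
        },
        sample_rate=fs,
    )


def resampled_zscore(x: np.ndarray, rate_in: float, rate_out: float, n_out: int) -> np.ndarray:
    """Anti-alias resample ``x`` to ``rate_out`` and z-score (ddof=0)."""
    frac = Fraction(rate_out).limit_denominator(10000) / Fraction(
        rate_in
    ).limit_denominator(10000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    if len(y) >= n_out:
        y = y[:n_out]
    else:
        y = np.concatenate([y, np.full(n_out - len(y), y[-1])])
    sd = y.std()
    return (y - y.mean()) / sd if sd > 0 else y - y.mean()


def delay_edge_hold(x: np.ndarray, shift: int) -> np.ndarray:
    """Delay by ``shift`` samples, holding the first value at the edge."""
    if shift <= 0:
        return x.copy()
    out = np.empty_like(x)
    out[:shift] = x[0]
    out[shift:] = x[: len(x) - shift]
    return out


def _channel_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    roi_blocks = np.array_split(np.arange(config.n_long_channels), len(config.rois))
    roi_of = np.empty(config.n_long_channels, dtype=object)
    for roi, block in zip(config.rois, roi_blocks):
        roi_of[block] = roi
    for i in range(config.n_long_channels):
        rows.append(
            {
                "name": f"S{i % 16 + 1}_D{i % 14 + 1}",
                "source": i % 16 + 1,
                "detector": i % 14 + 1,
                "separation_mm": config.long_separation_mm,
                "is_short": False,
                "roi": roi_of[i],
            }
        )
    for j in range(config.n_short_channels):
        rows.append(
            {
                "name": f"S{j % 16 + 1}_D{14 + j + 1}",
                "source": j % 16 + 1,
                "detector": 14 + j + 1,
                "separation_mm": config.short_separation_mm,
                "is_short": True,
                "roi": "scalp",
            }
        )
    return pd.DataFrame(rows)


def simulate_concentration(
    config: SimulationConfig,
    schedule: EventSchedule,
    physio: PhysioRecord,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """True concentration series (uM) for all channels plus ground truth."""
    fs = config.sample_rate_raw
    n_raw = int(round(config.session_duration * fs))
    table = _channel_table(config)
    n_total = len(table)
    conc = np.zeros((n_total, 2, n_raw))
    long_idx = np.flatnonzero(~table["is_short"].to_numpy())

    # session-level evoked amplitudes: a shared modulation plus per-ROI jitter
    shared = rng.normal(0.0, config.session_beta_sd)
    roi_amplitudes: dict[str, float] = {}
    for roi in config.rois:
        if roi in config.active_rois:
            roi_amplitudes[roi] = (
                config.speech_amplitude + shared + rng.normal(0.0, config.roi_beta_sd)
            )
        else:
            roi_amplitudes[roi] = 0.0

    reg_speech = stimulus_regressor(
        schedule.onsets_for("speech"), n_raw, fs, config.hrf_params, config.boxcar_width
    )
    reg_control = stimulus_regressor(
        schedule.onsets_for("control"), n_raw, fs, config.hrf_params, config.boxcar_width
    )

    channel_betas = np.zeros((n_total, 2, 2))  # chroma x (speech, control)
    for i in long_idx:
        roi = table.loc[i, "roi"]
        amp = roi_amplitudes[roi]
        camp = config.control_amplitude if roi in config.active_rois else 0.0
        evoked_hbo = amp * reg_speech + camp * reg_control
        conc[i, 0] += evoked_hbo
        conc[i, 1] += config.hbr_ratio * evoked_hbo
        channel_betas[i, 0] = (amp, camp)
        channel_betas[i, 1] = (config.hbr_ratio * amp, config.hbr_ratio * camp)

    # superficial (scalp) component: band-limited noise shared by all channels
    superficial = np.zeros((2, n_raw))
    if config.superficial_sd > 0:
        sos = sps.butter(
            4, config.superficial_band, btype="bandpass", fs=fs, output="sos"
        )
        for k, scale in enumerate((1.0, 1.0 / 3.0)):
            white = rng.standard_normal(n_raw)
            comp = sps.sosfiltfilt(sos, white)
            sd = comp.std()
            if sd > 0:
                comp = comp / sd
            superficial[k] = config.superficial_sd * scale * comp
    gains = config.superficial_gain * rng.uniform(0.5, 1.5, n_total)
    conc += gains[:, None, None] * superficial[None, :, :]

    # peripheral physiology coupled into long channels at known lags
    lags: dict[str, float] = {}
    for name, (gain, lag) in config.physio_couplings.items():
        lags[name] = lag
        if gain == 0.0:
            continue
        z = resampled_zscore(
            physio.signals[name], physio.sample_rate, fs, n_raw
        )
        shifted = delay_edge_hold(z, int(round(lag * fs)))
        conc[long_idx, 0] += gain * shifted
        conc[long_idx, 1] += gain * config.hbr_ratio * shifted

    if config.noise_sd > 0:
        conc += rng.normal(0.0, config.noise_sd, conc.shape)

    truth = GroundTruth(
        channel_betas=channel_betas,
        roi_amplitudes=roi_amplitudes,
        lags=lags,
        superficial=superficial,
        superficial_gains=gains,
        channel_table=table,
    )
    return conc, truth


def concentration_to_intensity(
    conc: np.ndarray,
    table: pd.DataFrame,
    ppf: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward model: uM concentration -> OD -> raw intensity (a.u.)."""
    separations_cm = table["separation_mm"].to_numpy() / 10.0
    od = forward_mbll(conc, separations_cm, ppf)
    baseline = rng.uniform(0.5, 2.0, (conc.shape[0], 2, 1))
    return baseline * np.exp(-od)


def _session_rng(config: SimulationConfig, session_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, session_index])


def generate_session(
    config: SimulationConfig, session_index: int = 0
) -> SessionBundle:
    """Generate one session: raw scan, physiology, events, and ground truth."""
    config.validate()
    if session_index >= config.n_sessions:
        raise InvalidInputError(
            f"session_index {session_index} >= n_sessions {config.n_sessions}"
        )
    rng = _session_rng(config, session_index)
    schedule = _draw_schedule(config, rng)
    physio = generate_physio(config, schedule, rng)
    conc, truth = simulate_concentration(config, schedule, physio, rng)
    intensity = concentration_to_intensity(conc, truth.channel_table, config.ppf, rng)
    raw = RawScan(
        intensity=intensity,
        sample_rate=config.sample_rate_raw,
        wavelengths=(760.0, 850.0),
        channel_table=truth.channel_table,
    )
    return SessionBundle(
        session_index=session_index,
        raw=raw,
        physio=physio,
        schedule=schedule,
        truth=truth,
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[SessionBundle], pd.DataFrame]:
    """All sessions plus a table of realized per-session ROI amplitudes."""
    config.validate()
    bundles = [generate_session(config, i) for i in range(config.n_sessions)]
    rows = []
    for b in bundles:
        for roi, amp in b.truth.roi_amplitudes.items():
            rows.append({"session": b.session_index, "roi": roi, "amplitude": amp})
    return bundles, pd.DataFrame(rows)
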