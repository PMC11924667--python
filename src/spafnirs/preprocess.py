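"""Raw intensity -> hemoglobin concentration preprocessing.

Stages (block-averaging path): optical density, scalp-coupling-index
pruning, temporal derivative distribution repair, modified Beer-Lambert
law, short-channel subtraction, and band-pass filtering.  The GLM path
uses only OD -> SCI pruning -> MBLL -> anti-aliased decimation, with no
temporal filtering, consistent with an unwhitened OLS analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import HemoTimeSeries, RawScan
from .errors import InvalidInputError

#: Molar extinction coefficients, cm^-1 / (mol / L), at the instrument's two
#: wavelengths (W.B. Gratzer's compiled hemoglobin spectra, as tabulated in
#: the HOMER toolbox).  Rows: wavelength (760, 850 nm); columns: (HbO, HbR).
EXTINCTION = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    try:
        e = np.array([EXTINCTION[w] for w in wavelengths])
    except KeyError as err:
        raise InvalidInputError(
            f"no extinction coefficients tabulated for wavelength {err}"
        ) from None
    if abs(np.linalg.det(e)) < 1e-12:
        raise InvalidInputError("extinction matrix is singular")
    return e


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters (defaults follow the study protocol)."""

    sci_threshold: float = 0.7
    sci_highpass_cutoff: float = 1.35  # Hz
    sci_transition_bw: float = 0.1  # Hz
    ppf: float = 0.1  # partial pathlength factor
    analysis_rate: float = 0.6  # Hz, GLM sample rate
    blockavg_band: tuple[float, float] = (0.02, 0.4)  # Hz
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def validate(self) -> None:
        if not 0.0 <= self.sci_threshold <= 1.0:
            raise InvalidInputError("sci_threshold must be in [0, 1]")
        if self.analysis_rate <= 0:
            raise InvalidInputError("analysis_rate must be positive")


# ---------------------------------------------------------------------------
# optical density
# ---------------------------------------------------------------------------

def intensity_to_od(scan: RawScan) -> np.ndarray:
    """Optical density change: ``-ln(I / mean(I))`` per channel/wavelength."""
    intensity = scan.intensity
    if np.any(intensity <= 0):
        bad = np.argwhere(intensity <= 0)[0]
        name = scan.channel_table.loc[bad[0], "name"]
        raise InvalidInputError(
            f"non-positive intensity in channel {name} "
            f"(wavelength index {bad[1]}, sample {bad[2]})"
        )
    mean = intensity.mean(axis=2, keepdims=True)
    return -np.log(intensity / mean)


# ---------------------------------------------------------------------------
# scalp coupling index
# ---------------------------------------------------------------------------

def _sci_filter(sample_rate: float, cutoff: float, transition_bw: float) -> np.ndarray:
    """High-pass FIR (Hamming) with the given cutoff and transition width."""
    numtaps = int(np.ceil(3.3 * sample_rate / transition_bw))
    numtaps += 1 - numtaps % 2  # high-pass FIR needs odd length
    nyq = sample_rate / 2.0
    if cutoff >= nyq:
        raise InvalidInputError(
            f"SCI cutoff {cutoff} Hz is not below Nyquist {nyq} Hz"
        )
    return sps.firwin(numtaps, cutoff, fs=sample_rate, pass_zero=False)


def scalp_coupling_index(
    od: np.ndarray, sample_rate: float, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel SCI and keep mask.

    SCI is the Pearson correlation between the two wavelengths' high-pass
    filtered OD (cardiac band); channels with SCI below the threshold are
    flagged for removal.  Must run at the native rate, before decimation.
    """
    cfg = cfg or PreprocessConfig()
    taps = _sci_filter(sample_rate, cfg.sci_highpass_cutoff, cfg.sci_transition_bw)
    n_times = od.shape[2]
    if n_times <= 3 * len(taps):
        raise InvalidInputError(
            f"series too short ({n_times} samples) for SCI filter of "
            f"{len(taps)} taps"
        )
    filtered = sps.filtfilt(taps, [1.0], od, axis=2)
    a = filtered[:, 0, :]
    b = filtered[:, 1, :]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        sci = np.where(denom > 0, (a * b).sum(axis=1) / denom, 0.0)
    return sci, sci >= cfg.sci_threshold


# ---------------------------------------------------------------------------
# temporal derivative distribution repair
# ---------------------------------------------------------------------------

def _tddr_1d(series: np.ndarray, sample_rate: float, tol: float = 1e-9) -> np.ndarray:
    """Motion-artifact repair of one uniformly sampled series.

    Robust iterative reweighting (Tukey biweight) of the temporal
    derivative of the low-frequency (<0.5 Hz) part of the signal, followed
    by reintegration; frequencies above 0.5 Hz are passed through.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0.0:
        return x.copy()
    mean = x.mean()
    centered = x - mean
    cutoff = 0.5  # Hz
    wn = cutoff * 2.0 / sample_rate
    if wn < 1.0:
        fb, fa = sps.butter(3, wn)
        low = sps.filtfilt(fb, fa, centered, padlen=0)
    else:
        low = centered
    high = centered - low

    deriv = np.diff(low)
    w = np.ones_like(deriv)
    mu = np.inf
    tune = 4.685
    for _ in range(50):
        mu0 = mu
        mu = np.sum(w * deriv) / np.sum(w)
        dev = np.abs(deriv - mu)
        sigma = 1.4826 * np.median(dev)
        if sigma == 0.0:
            break
        r = dev / (sigma * tune)
        w = ((1.0 - r**2) * (r < 1.0)) ** 2
        if np.isfinite(mu0) and abs(mu - mu0) < tol * max(abs(mu), abs(mu0)):
            break
    repaired = np.concatenate(([0.0], np.cumsum(w * (deriv - mu))))
    repaired -= repaired.mean()  # reintegration loses the DC level
    return repaired + high + mean


def tddr(series: np.ndarray, sample_rate: float) -> np.ndarray:
    """Apply TDDR along the last axis of an array of series."""
    arr = np.asarray(series, dtype=float)
    out = np.empty_like(arr)
    flat_in = arr.reshape(-1, arr.shape[-1])
    flat_out = out.reshape(-1, arr.shape[-1])
    for i in range(flat_in.shape[0]):
        flat_out[i] = _tddr_1d(flat_in[i], sample_rate)
    return out


# ---------------------------------------------------------------------------
# modified Beer-Lambert law
# ---------------------------------------------------------------------------

def forward_mbll(
    conc_um: np.ndarray, separations_cm: np.ndarray, ppf: float,
    wavelengths: tuple[float, float] = (760.0, 850.0),
) -> np.ndarray:
    """uM concentration (n_ch, 2 chroma, t) -> OD change (n_ch, 2 wl, t)."""
    e = extinction_matrix(wavelengths)
    conc_molar = np.asarray(conc_um) * 1e-6
    od = np.einsum("wc,nct->nwt", e, conc_molar)
    return od * (np.asarray(separations_cm)[:, None, None] * ppf)


def od_to_hemoglobin(
    od: np.ndarray,
    scan_or_table,
    cfg: PreprocessConfig | None = None,
    sample_rate: float | None = None,
) -> HemoTimeSeries:
    """Invert the modified Beer-Lambert law per channel.

    Solves the 2x2 extinction system ``dOD_l = (e_HbO,l dHbO + e_HbR,l
    dHbR) * d * PPF`` at every time point; concentrations are returned
    in uM.
    """
    cfg = cfg or PreprocessConfig()
    if isinstance(scan_or_table, RawScan):
        table = scan_or_table.channel_table
        rate = scan_or_table.sample_rate
        wavelengths = scan_or_table.wavelengths
    else:
        table = scan_or_table
        rate = sample_rate
        wavelengths = cfg.wavelengths
        if rate is None:
            raise InvalidInputError("sample_rate required when passing a table")
    e = extinction_matrix(wavelengths)
    e_inv = np.linalg.inv(e)
    separations_cm = table["separation_mm"].to_numpy() / 10.0
    scaled = np.asarray(od) / (separations_cm[:, None, None] * cfg.ppf)
    conc_molar = np.einsum("cw,nwt->nct", e_inv, scaled)
    return HemoTimeSeries(
        concentration=conc_molar * 1e6,
        sample_rate=rate,
        channel_table=table.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------

def _resample_fraction(rate_in: float, rate_out: float) -> Fraction:
    return Fraction(rate_out).limit_denominator(10000) / Fraction(
        rate_in
    ).limit_denominator(10000)


def bandpass_and_resample(
    hemo: HemoTimeSeries,
    band: tuple[float, float] | None = None,
    target_rate: float | None = None,
) -> HemoTimeSeries:
    """Zero-phase band-pass and/or anti-aliased decimation.

    ``band=None`` skips filtering (the GLM path); ``target_rate=None``
    keeps the native rate (the block-averaging path).
    """
    data = hemo.concentration
    rate = hemo.sample_rate
    if band is not None and target_rate is not None and band[1] >= target_rate / 2.0:
        raise InvalidInputError(
            f"band upper edge {band[1]} Hz not below target Nyquist "
            f"{target_rate / 2.0} Hz"
        )
    if band is not None:
        lo, hi = band
        if hi >= rate / 2.0:
            raise InvalidInputError("band upper edge not below current Nyquist")
        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=rate, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=2)
    if target_rate is not None and target_rate != rate:
        if target_rate > rate:
            raise InvalidInputError("target_rate must not exceed the current rate")
        frac = _resample_fraction(rate, target_rate)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=2)
        rate = target_rate
    return HemoTimeSeries(
        concentration=np.ascontiguousarray(data),
        sample_rate=rate,
        channel_table=hemo.channel_table,
    )


# ---------------------------------------------------------------------------
# short-channel subtraction
# ---------------------------------------------------------------------------

def short_channel_reference(hemo: HemoTimeSeries) -> np.ndarray:
    """Chroma-matched reference: mean of surviving short channels, (2, t)."""
    short = hemo.concentration[hemo.short_mask]
    if short.shape[0] == 0:
        raise InvalidInputError("no short channels available")
    return short.mean(axis=0)


def short_channel_subtract(hemo: HemoTimeSeries) -> HemoTimeSeries:
    """Subtract the least-squares-scaled short-channel reference.

    For each long channel and chroma the reference (mean of surviving
    short channels of the same chroma) is scaled by its least-squares
    coefficient and removed; the residual is orthogonal to the reference.
    Short channels pass through unchanged.  With no short channels the
    input is returned unchanged with a warning.
    """
    if not hemo.short_mask.any():
        import warnings

        warnings.warn("no short channels; returning input unchanged", stacklevel=2)
        return hemo.copy()
    ref = short_channel_reference(hemo)  # (2, t)
    out = hemo.concentration.copy()
    long_idx = np.flatnonzero(hemo.long_mask)
    for k in range(2):
        r = ref[k]
        denom = r @ r
        if denom == 0:
            continue
        scale = out[long_idx, k, :] @ r / denom  # per long channel
        out[long_idx, k, :] -= scale[:, None] * r[None, :]
    return HemoTimeSeries(
        concentration=out,
        sample_rate=hemo.sample_rate,
        channel_table=hemo.channel_table,
    )


# ---------------------------------------------------------------------------
# composite paths
# ---------------------------------------------------------------------------

def glm_path(
    scan: RawScan, cfg: PreprocessConfig | None = None
) -> tuple[HemoTimeSeries, np.ndarray]:
    """OD -> SCI pruning -> MBLL -> decimation; no temporal filtering.

    Returns the analysis-rate concentration series of surviving channels
    and the per-channel SCI values of the original scan.
    """
    cfg = cfg or PreprocessConfig()
    od = intensity_to_od(scan)
    sci, keep = scalp_coupling_index(od, scan.sample_rate, cfg)
    pruned = scan.select(keep)
    hemo = od_to_hemoglobin(od[keep], pruned, cfg)
    hemo = bandpass_and_resample(hemo, band=None, target_rate=cfg.analysis_rate)
    return hemo, sci


def blockavg_path(
    scan: RawScan, cfg: PreprocessConfig | None = None
) -> tuple[HemoTimeSeries, np.ndarray]:
    """OD -> SCI pruning -> TDDR -> MBLL -> SS subtraction -> band-pass.

    Stays at the native rate (the 0.02-0.4 Hz band does not fit below the
    0.6 Hz analysis-rate Nyquist).
    """
    cfg = cfg or PreprocessConfig()
    od = intensity_to_od(scan)
    sci, keep = scalp_coupling_index(od, scan.sample_rate, cfg)
    pruned = scan.select(keep)
    od_fixed = tddr(od[keep], scan.sample_rate)
    hemo = od_to_hemoglobin(od_fixed, pruned, cfg)
    hemo = short_channel_subtract(hemo)
    hemo = bandpass_and_resample(hemo, band=cfg.blockavg_band, target_rate=None)
    return hemo, sci
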