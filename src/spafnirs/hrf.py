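"""Canonical hemodynamic response model.

The stimulus regressor is the SPM-style double-gamma impulse response
convolved with a 3 s boxcar, placed at each stimulus onset.  The combined
kernel is normalized to unit peak so a regression coefficient on this
column is directly interpretable as the evoked response amplitude in the
units of the data (uM here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma shape parameters (SPM convention, seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0  # peak-to-undershoot amplitude ratio
    duration: float = 32.0  # kernel support


def double_gamma(t: np.ndarray, params: HrfParams | None = None) -> np.ndarray:
    """Evaluate the double-gamma impulse response at times ``t`` (s)."""
    p = params or HrfParams()
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    undershoot = gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - undershoot / p.ratio
    h[t < 0] = 0.0
    return h


def stimulus_kernel(
    sample_rate: float,
    params: HrfParams | None = None,
    boxcar_width: float = 3.0,
) -> np.ndarray:
    """HRF convolved with a ``boxcar_width`` s boxcar, unit peak amplitude."""
    p = params or HrfParams()
    dt = 1.0 / sample_rate
    t = np.arange(0.0, p.duration + boxcar_width, dt)
    h = double_gamma(t, p)
    n_box = max(1, int(round(boxcar_width * sample_rate)))
    box = np.ones(n_box)
    kernel = np.convolve(h, box)[: len(t)] * dt
    peak = np.max(np.abs(kernel))
    if peak > 0:
        kernel = kernel / peak
    return kernel


def stimulus_regressor(
    onsets: np.ndarray,
    n_times: int,
    sample_rate: float,
    params: HrfParams | None = None,
    boxcar_width: float = 3.0,
) -> np.ndarray:
    """Unit-peak HRF x boxcar response train for the given onsets."""
    stick = np.zeros(n_times)
    idx = np.round(np.asarray(onsets, dtype=float) * sample_rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n_times)]
    stick[idx] = 1.0
    kernel = stimulus_kernel(sample_rate, params, boxcar_width)
    return np.convolve(stick, kernel)[:n_times]
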