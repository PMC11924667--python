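"""Physiology nuisance regressors: conditioning, lag search, and tCCA.

Peripheral signals are low-pass filtered where required (GSR at 5 Hz;
everything at 0.5 Hz on the tCCA path), anti-alias downsampled,
interpolated onto the fNIRS analysis time axis, and z-scored.  The lag
model delays each regressor on a 0-30 s grid and keeps the delay with the
highest cross-correlation per channel.  The tCCA model stacks delayed
copies of each signal and extracts canonical components shared with the
multichannel fNIRS matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import PHYSIO_SIGNALS, PhysioRecord
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

ANALYSIS_STEP = 1.0 / 0.6  # s, one sample at the 0.6 Hz analysis rate


@dataclass
class ConditionedRegressor:
    """A z-scored physiology regressor on the fNIRS analysis axis."""

    values: np.ndarray
    name: str
    applied_lag: float = 0.0  # s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class LagConfig:
    """Grid for the per-channel cross-correlation lag search."""

    min_lag: float = 0.0  # s
    max_lag: float = 30.0  # s
    step: float = ANALYSIS_STEP  # s; one analysis-rate sample by default
    use_abs: bool = False  # rank by |r| instead of signed r

    def validate(self) -> None:
        if not (0.0 <= self.min_lag < self.max_lag):
            raise InvalidInputError("need 0 <= min_lag < max_lag")
        if self.step <= 0:
            raise InvalidInputError("lag step must be positive")

    def grid(self) -> np.ndarray:
        self.validate()
        return np.arange(self.min_lag, self.max_lag + 1e-9, self.step)


@dataclass
class TccaConfig:
    """Temporally embedded CCA parameters."""

    rho_threshold: float = 0.3
    prefilter_cutoff: float = 0.5  # Hz, applied at the native physiology rate
    embed_lags: tuple[float, ...] | None = None  # s; default 0-30 s analysis grid
    max_components: int | None = None
    ridge: float = 1e-8
    selection: str = "cv"  # "cv" (two-fold cross-estimated rho) or "insample"

    def validate(self) -> None:
        if not 0.0 < self.rho_threshold < 1.0:
            raise InvalidInputError("rho_threshold must be in (0, 1)")
        if self.embed_lags is not None and any(l < 0 for l in self.embed_lags):
            raise InvalidInputError("embed lags must be non-negative")
        if self.selection not in ("cv", "insample"):
            raise InvalidInputError("selection must be 'cv' or 'insample'")

    def lags(self) -> np.ndarray:
        self.validate()
        if self.embed_lags is not None:
            return np.asarray(self.embed_lags, dtype=float)
        return np.arange(0.0, 30.0 + 1e-9, ANALYSIS_STEP)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidInputError("cannot z-score a constant signal")
    return (x - x.mean()) / sd


def condition_physio(
    record: PhysioRecord,
    target_times: np.ndarray,
    analysis_rate: float = 0.6,
    gsr_lowpass: float = 5.0,
    prefilter_cutoff: float | None = None,
) -> dict[str, ConditionedRegressor]:
    """Prepare all six signals as GLM regressors on the fNIRS time axis.

    GSR is low-pass filtered at ``gsr_lowpass`` Hz at the native rate
    first; ``prefilter_cutoff`` (the tCCA path) low-passes *every* signal.
    Each signal is then anti-alias downsampled to the analysis rate,
    linearly interpolated onto ``target_times``, and z-scored.
    """
    target_times = np.asarray(target_times, dtype=float)
    if record.duration < target_times[-1]:
        raise InvalidInputError(
            f"physiology record ({record.duration:.1f} s) shorter than the "
            f"fNIRS span ({target_times[-1]:.1f} s)"
        )
    frac = Fraction(analysis_rate).limit_denominator(10000) / Fraction(
        record.sample_rate
    ).limit_denominator(10000)
    out: dict[str, ConditionedRegressor] = {}
    for name in PHYSIO_SIGNALS:
        x = record.signals[name]
        if name == "gsr" and gsr_lowpass is not None:
            sos = sps.butter(
                4, gsr_lowpass, btype="lowpass", fs=record.sample_rate, output="sos"
            )
            x = sps.sosfiltfilt(sos, x)
        if prefilter_cutoff is not None:
            sos = sps.butter(
                4, prefilter_cutoff, btype="lowpass", fs=record.sample_rate, output="sos"
            )
            x = sps.sosfiltfilt(sos, x)
        y = sps.resample_poly(x, frac.numerator, frac.denominator)
        t_y = np.arange(len(y)) / analysis_rate
        interp = np.interp(target_times, t_y, y)
        out[name] = ConditionedRegressor(values=_zscore(interp), name=name)
    return out


# ---------------------------------------------------------------------------
# lag search
# ---------------------------------------------------------------------------

def delay_samples(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift a regressor forward in time by ``shift`` samples (edge-held)."""
    if shift <= 0:
        return np.asarray(x, dtype=float).copy()
    out = np.empty_like(np.asarray(x, dtype=float))
    out[:shift] = x[0]
    out[shift:] = x[: len(x) - shift]
    return out


def find_optimal_lag(
    regressor: ConditionedRegressor | np.ndarray,
    channel: np.ndarray,
    cfg: LagConfig | None = None,
    sample_rate: float = 0.6,
) -> tuple[float, float]:
    """Exhaustive grid search for the delay maximizing cross-correlation.

    The regressor is shifted forward (physiology precedes its vascular
    echo) and the Pearson correlation with the channel is evaluated on the
    overlapping support.  Ties break toward the smaller lag.
    """
    cfg = cfg or LagConfig()
    r = regressor.values if isinstance(regressor, ConditionedRegressor) else regressor
    r = np.asarray(r, dtype=float)
    y = np.asarray(channel, dtype=float)
    if len(r) != len(y):
        raise InvalidInputError("regressor and channel lengths differ")
    if r.std() == 0 or y.std() == 0:
        raise InvalidInputError("correlation undefined for a constant series")
    best_lag, best_r, best_score = None, None, -np.inf
    for lag in cfg.grid():
        shift = int(round(lag * sample_rate))
        if shift >= len(r) - 2:
            break
        a = r[: len(r) - shift] if shift else r
        b = y[shift:] if shift else y
        if a.std() == 0 or b.std() == 0:
            continue
        rho = float(np.corrcoef(a, b)[0, 1])
        score = abs(rho) if cfg.use_abs else rho
        if score > best_score:
            best_lag, best_r, best_score = float(lag), rho, score
    if best_lag is None:
        raise InvalidInputError("empty lag grid")
    return best_lag, best_r


def find_optimal_lags(
    regressor: ConditionedRegressor | np.ndarray,
    channels: np.ndarray,
    cfg: LagConfig | None = None,
    sample_rate: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized lag search over a ``(n_series, n_times)`` channel matrix."""
    cfg = cfg or LagConfig()
    r = regressor.values if isinstance(regressor, ConditionedRegressor) else regressor
    r = np.asarray(r, dtype=float)
    Y = np.atleast_2d(np.asarray(channels, dtype=float))
    grid = cfg.grid()
    scores = np.full((len(grid), Y.shape[0]), -np.inf)
    rhos = np.zeros((len(grid), Y.shape[0]))
    for gi, lag in enumerate(grid):
        shift = int(round(lag * sample_rate))
        if shift >= len(r) - 2:
            break
        a = r[: len(r) - shift] if shift else r
        B = Y[:, shift:] if shift else Y
        ac = a - a.mean()
        Bc = B - B.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac**2).sum() * (Bc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, Bc @ ac / denom, 0.0)
        rhos[gi] = rho
        scores[gi] = np.abs(rho) if cfg.use_abs else rho
    best = scores.argmax(axis=0)  # first max -> smaller lag on ties
    return grid[best], rhos[best, np.arange(Y.shape[0])]


# ---------------------------------------------------------------------------
# canonical correlation analysis
# ---------------------------------------------------------------------------

def _zscore_cols(M: np.ndarray, mean=None, sd=None):
    mean = M.mean(axis=0) if mean is None else mean
    sd = M.std(axis=0) if sd is None else sd
    sd = np.where(sd > 0, sd, 1.0)
    return (M - mean) / sd, mean, sd


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    vals = np.maximum(vals, 1e-12 * vals.max())
    return (vecs / np.sqrt(vals)) @ vecs.T


def cca(
    X: np.ndarray, Y: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlations and weights via whitened cross-covariance SVD.

    Returns ``(rho, Wx, Wy)`` with ``rho`` sorted descending in [0, 1];
    variates are ``Xc @ Wx`` and ``Yc @ Wy`` on column-standardized data.
    """
    Xc, _, _ = _zscore_cols(np.asarray(X, dtype=float))
    Yc, _, _ = _zscore_cols(np.asarray(Y, dtype=float))
    n = Xc.shape[0]
    Cxx = Xc.T @ Xc / n + ridge * np.eye(Xc.shape[1])
    Cyy = Yc.T @ Yc / n + ridge * np.eye(Yc.shape[1])
    Cxy = Xc.T @ Yc / n
    cond = np.linalg.cond(Cxx)
    if cond > 1e10:
        logger.info("embedded covariance condition number %.3g; ridge %.1e", cond, ridge)
    Kx = _inv_sqrt(Cxx)
    Ky = _inv_sqrt(Cyy)
    U, s, Vt = np.linalg.svd(Kx @ Cxy @ Ky)
    k = min(Xc.shape[1], Yc.shape[1])
    rho = np.clip(s[:k], 0.0, 1.0)
    Wx = Kx @ U[:, :k]
    Wy = Ky @ Vt.T[:, :k]
    return rho, Wx, Wy


def embed_regressors(
    regressors: dict[str, ConditionedRegressor] | list[ConditionedRegressor],
    lags_s: np.ndarray,
    sample_rate: float,
) -> tuple[np.ndarray, list[str]]:
    """Stack forward-delayed copies of each regressor (edge-held)."""
    if isinstance(regressors, dict):
        regressors = [regressors[k] for k in sorted(regressors)]
    cols, names = [], []
    for reg in regressors:
        for lag in lags_s:
            shift = int(round(lag * sample_rate))
            cols.append(delay_samples(reg.values, shift))
            names.append(f"{reg.name}@{lag:.2f}s")
    return np.column_stack(cols), names


@dataclass
class TccaResult:
    """Selected latent physiology components and their correlations."""

    components: np.ndarray  # (n_times, n_selected)
    selected: np.ndarray  # indices into the full component list
    rho: np.ndarray  # in-sample canonical correlations, descending
    rho_selection: np.ndarray  # correlations used for thresholding
    column_names: list[str] = field(default_factory=list)


def tcca_select_components(
    regressors: dict[str, ConditionedRegressor] | list[ConditionedRegressor],
    fnirs: np.ndarray,
    cfg: TccaConfig | None = None,
    sample_rate: float = 0.6,
) -> TccaResult:
    """Temporally embedded CCA between physiology and the fNIRS matrix.

    ``fnirs`` is ``(n_series, n_times)`` (all channels/chroma).  Canonical
    correlations are reported in-sample; component *selection* against the
    0.3 threshold uses a two-fold cross-estimated correlation by default,
    since in-sample canonical correlations of a wide embedded matrix are
    biased upward on a single session.
    """
    cfg = cfg or TccaConfig()
    cfg.validate()
    Y = np.atleast_2d(np.asarray(fnirs, dtype=float)).T  # (n_times, n_series)
    X, names = embed_regressors(regressors, cfg.lags(), sample_rate)
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("physiology and fNIRS lengths differ")
    if Y.std(axis=0).max() == 0:
        raise InvalidInputError("fNIRS matrix is degenerate (constant)")

    rho_in, Wx, Wy = cca(X, Y, ridge=cfg.ridge)

    if cfg.selection == "insample":
        rho_sel = rho_in
    else:
        n = X.shape[0]
        half = n // 2
        folds = ((slice(0, half), slice(half, n)), (slice(half, n), slice(0, half)))
        rho_folds = []
        for train, test in folds:
            Xtr, mx, sx = _zscore_cols(X[train])
            Ytr, my, sy = _zscore_cols(Y[train])
            r_tr, Wx_tr, Wy_tr = cca(Xtr, Ytr, ridge=cfg.ridge)
            Xte = (X[test] - mx) / np.where(sx > 0, sx, 1.0)
            Yte = (Y[test] - my) / np.where(sy > 0, sy, 1.0)
            U = Xte @ Wx_tr
            V = Yte @ Wy_tr
            Uc = U - U.mean(axis=0)
            Vc = V - V.mean(axis=0)
            denom = np.sqrt((Uc**2).sum(axis=0) * (Vc**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r_te = np.where(denom > 0, (Uc * Vc).sum(axis=0) / denom, 0.0)
            rho_folds.append(np.abs(r_te))
        rho_sel = np.mean(rho_folds, axis=0)

    selected = np.flatnonzero(rho_sel >= cfg.rho_threshold)
    if cfg.max_components is not None:
        selected = selected[: cfg.max_components]
    Xc, _, _ = _zscore_cols(X)
    components = Xc @ Wx[:, selected] if len(selected) else np.empty((X.shape[0], 0))
    return TccaResult(
        components=components,
        selected=selected,
        rho=rho_in,
        rho_selection=rho_sel,
        column_names=[f"tcca_{k}" for k in selected],
    )
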