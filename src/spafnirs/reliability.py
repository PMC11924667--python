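"""Test-retest reliability: ICC(3,k) and session-to-session variance.

Sessions are the targets (rows), ROIs the raters (columns), and
speech-condition beta estimates the ratings.  ICC(3,k) is the Shrout &
Fleiss two-way mixed-model consistency coefficient for the average of k
raters: ``(BMS - EMS) / BMS`` from the two-way ANOVA decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

#: interpretation cut points (left-closed intervals)
BANDS = (("poor", 0.40), ("fair", 0.60), ("good", 0.75), ("excellent", 1.01))


def band_label(icc: float) -> str | None:
    """Reliability band for an ICC value: poor/fair/good/excellent."""
    if not np.isfinite(icc):
        return None
    for label, upper in BANDS:
        if icc < upper:
            return label
    return "excellent"


@dataclass
class ReliabilityResult:
    icc: float
    band: str | None
    F: float
    df1: int
    df2: int
    p: float
    bms: float  # between-targets (sessions) mean square
    ems: float  # residual mean square
    n_targets: int
    n_raters: int
    note: str = ""


def icc_3k(ratings) -> ReliabilityResult:
    """ICC(3,k) from a sessions x ROIs ratings matrix.

    Accepts a 2-D array or a wide DataFrame (rows = sessions).  Rows with
    any missing cell are dropped pairwise.
    """
    if isinstance(ratings, pd.DataFrame):
        ratings = ratings.dropna().to_numpy(dtype=float)
    M = np.asarray(ratings, dtype=float)
    if M.ndim != 2:
        raise InvalidInputError("ratings must be a 2-D sessions x raters matrix")
    M = M[~np.isnan(M).any(axis=1)]
    n, k = M.shape
    if n < 2 or k < 2:
        raise InvalidInputError("need at least 2 sessions and 2 raters")

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    bms = ss_rows / df1
    ems = ss_err / df2

    if bms <= 0.0:
        return ReliabilityResult(
            icc=np.nan, band=None, F=np.nan, df1=df1, df2=df2, p=np.nan,
            bms=bms, ems=ems, n_targets=n, n_raters=k,
            note="zero between-session variance; ICC undefined",
        )
    icc = (bms - ems) / bms
    F = bms / ems if ems > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ReliabilityResult(
        icc=float(icc), band=band_label(icc), F=float(F), df1=df1, df2=df2,
        p=p, bms=float(bms), ems=float(ems), n_targets=n, n_raters=k,
    )


def ratings_matrix(
    roi_betas: pd.DataFrame,
    model: str,
    chroma: str,
    condition: str = "speech",
) -> pd.DataFrame:
    """Sessions x ROIs wide matrix of betas for one model and chromophore."""
    sel = roi_betas[
        (roi_betas["model"] == model)
        & (roi_betas["chroma"] == chroma)
        & (roi_betas["condition"] == condition)
    ]
    if sel.empty:
        raise InvalidInputError(
            f"no betas for model={model!r}, chroma={chroma!r}, condition={condition!r}"
        )
    return sel.pivot_table(index="session", columns="roi", values="beta")


def session_variance(values: np.ndarray) -> float:
    """Sample variance (n-1 denominator) of session-level betas."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InvalidInputError("need at least two sessions")
    return float(np.var(v, ddof=1))


def session_variance_table(roi_betas: pd.DataFrame) -> pd.DataFrame:
    """Per (model, roi, chroma, condition) variance of betas across sessions."""
    group_cols = [
        c for c in ("model", "roi", "chroma", "condition") if c in roi_betas.columns
    ]
    out = (
        roi_betas.groupby(group_cols, sort=True)["beta"]
        .agg(variance=lambda v: np.var(v, ddof=1), n_sessions="count")
        .reset_index()
    )
    out["n_sessions"] = out["n_sessions"].astype(int)
    return out
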