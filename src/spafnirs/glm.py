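"""Six-model GLM construction, OLS fitting, ROI aggregation, and tests.

The correction models are: ``none`` (stimulus + intercept only),
``physio`` (six peripheral signals), ``ss`` (chroma-mean short channels),
``ss_physio`` (union), ``ss_physio_lag`` (per-channel lag-optimized
physiology + short channels), and ``ss_tcca`` (tCCA latent components +
short channels).  Fitting is plain ordinary least squares on the
unfiltered analysis-rate series: no pre-whitening, pre-coloring, or drift
regressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EventSchedule
from .errors import InvalidInputError, RankDeficiencyError
from .hrf import HrfParams, stimulus_regressor

MODELS = ("none", "physio", "ss", "ss_physio", "ss_physio_lag", "ss_tcca")

#: regressor groups a model's design may carry besides stimulus + intercept
MODEL_GROUPS = {
    "none": frozenset(),
    "physio": frozenset({"physio"}),
    "ss": frozenset({"ss"}),
    "ss_physio": frozenset({"ss", "physio"}),
    "ss_physio_lag": frozenset({"ss", "lag_physio"}),
    "ss_tcca": frozenset({"ss", "tcca"}),
}

NUISANCE_GROUPS = ("physio", "ss", "lag_physio", "tcca")


@dataclass
class DesignMatrix:
    """Named regressor columns plus their group labels for one model."""

    data: pd.DataFrame  # rows = analysis samples, columns = regressors
    groups: dict[str, str]  # column -> group label
    model: str

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InvalidInputError(f"unknown model {self.model!r}")
        if self.data.columns.duplicated().any():
            raise InvalidInputError("design matrix column names must be unique")
        zero = [c for c in self.data.columns if np.allclose(self.data[c], 0.0)]
        if zero:
            raise InvalidInputError(f"all-zero design columns: {zero}")
        if set(self.groups) != set(self.data.columns):
            raise InvalidInputError("groups must label every design column")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def columns_in_group(self, group: str) -> list[str]:
        return [c for c, g in self.groups.items() if g == group]


def build_design_matrix(
    model: str,
    schedule: EventSchedule,
    n_times: int,
    sample_rate: float,
    hrf_params: HrfParams | None = None,
    boxcar_width: float = 3.0,
    physio_regressors: dict[str, np.ndarray] | None = None,
    short_channels: dict[str, np.ndarray] | None = None,
    tcca_components: dict[str, np.ndarray] | None = None,
    lagged_physio: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """Assemble the design for one correction model.

    Stimulus columns are the canonical double-gamma HRF convolved with a
    3 s boxcar at speech and control onsets; an intercept is always
    included.  ``lagged_physio`` carries the per-channel delayed
    regressors for the lag model (one design per channel).
    """
    if model not in MODELS:
        raise InvalidInputError(f"unknown model {model!r}; expected one of {MODELS}")
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for condition in ("speech", "control"):
        onsets = schedule.onsets_for(condition)
        if len(onsets) == 0:  # a condition absent from the schedule
            continue
        cols[condition] = stimulus_regressor(
            onsets, n_times, sample_rate, hrf_params, boxcar_width
        )
        groups[condition] = "stimulus"

    def add(group: str, source: dict[str, np.ndarray] | None, what: str) -> None:
        if not source:
            raise InvalidInputError(f"model {model!r} requires {what}")
        for name, values in source.items():
            values = np.asarray(values, dtype=float)
            if len(values) != n_times:
                raise InvalidInputError(f"regressor {name!r} length mismatch")
            cols[name] = values
            groups[name] = group

    needed = MODEL_GROUPS[model]
    if "physio" in needed:
        add("physio", physio_regressors, "six conditioned physiology regressors")
    if "ss" in needed:
        add("ss", short_channels, "surviving short-channel regressors")
    if "lag_physio" in needed:
        add("lag_physio", lagged_physio, "per-channel lagged physiology regressors")
    if "tcca" in needed:
        if tcca_components is None:
            raise InvalidInputError("model 'ss_tcca' requires tCCA components")
        # zero selected components is a legitimate outcome of the threshold
        for name, values in tcca_components.items():
            cols[name] = np.asarray(values, dtype=float)
            groups[name] = "tcca"

    cols["intercept"] = np.ones(n_times)
    groups["intercept"] = "intercept"
    return DesignMatrix(data=pd.DataFrame(cols), groups=groups, model=model)


@dataclass
class GlmResult:
    """Per-series OLS estimates for one design."""

    beta: np.ndarray  # (n_series, p)
    se: np.ndarray  # (n_series, p)
    rmse: np.ndarray  # (n_series,), sqrt(RSS / n)
    dof: int  # n - p
    columns: list[str]
    model: str

    def coef(self, column: str) -> np.ndarray:
        return self.beta[:, self.columns.index(column)]

    def coef_se(self, column: str) -> np.ndarray:
        return self.se[:, self.columns.index(column)]


def fit_ols(Y: np.ndarray, X: DesignMatrix) -> GlmResult:
    """Ordinary least squares of each row of ``Y`` on the design.

    ``beta = (X'X)^-1 X'y``; standard errors from the sigma^2 (X'X)^-1
    diagonal with sigma^2 = RSS / (n - p); ``rmse = sqrt(RSS / n)``.
    """
    Y2 = np.atleast_2d(np.asarray(Y, dtype=float))
    Xv = X.values
    n, p = Xv.shape
    if Y2.shape[1] != n:
        raise InvalidInputError(
            f"design has {n} rows but data has {Y2.shape[1]} samples"
        )
    if n <= p:
        raise InvalidInputError(f"need more samples ({n}) than regressors ({p})")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # identify offending columns via the QR diagonal
        _, R = np.linalg.qr(Xv)
        bad = [X.columns[i] for i in range(p) if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise RankDeficiencyError(f"design matrix rank deficient; collinear: {bad}")
    gram = Xv.T @ Xv
    gram_inv = np.linalg.inv(gram)
    beta = Y2 @ Xv @ gram_inv.T  # (n_series, p)
    resid = Y2 - beta @ Xv.T
    rss = np.sum(resid**2, axis=1)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.outer(sigma2, np.diag(gram_inv)))
    rmse = np.sqrt(rss / n)
    return GlmResult(
        beta=beta, se=se, rmse=rmse, dof=n - p, columns=X.columns, model=X.model
    )


def roi_weighted_average(channel_results: pd.DataFrame) -> pd.DataFrame:
    """Inverse-standard-error weighted ROI averages of channel betas.

    Expects a tidy frame with columns ``roi, chroma, condition, beta, se``
    (plus any grouping columns such as ``model`` or ``session``); returns
    one row per group with ``beta = sum(b/se) / sum(1/se)`` and the mean
    channel RMSE if an ``rmse`` column is present.
    """
    required = {"roi", "chroma", "condition", "beta", "se"}
    missing = required - set(channel_results.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    group_cols = [
        c
        for c in ("session", "model", "roi", "chroma", "condition")
        if c in channel_results.columns
    ]

    def agg(g: pd.DataFrame) -> pd.Series:
        w = 1.0 / g["se"].to_numpy()
        out = {"beta": float(np.sum(w * g["beta"])) / float(np.sum(w)),
               "n_channels": len(g)}
        if "rmse" in g.columns:
            out["rmse"] = float(g["rmse"].mean())
        return pd.Series(out)

    result = (
        channel_results.groupby(group_cols, sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    result["n_channels"] = result["n_channels"].astype(int)
    return result


def one_sample_test(values: np.ndarray, alpha: float = 0.0025):
    """One-sample t-test of mean != 0; degenerate cases handled explicitly."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InvalidInputError("need at least two observations")
    if v.std(ddof=1) == 0.0:
        if v.mean() == 0.0:
            return 0.0, 1.0, False
        return np.inf, np.finfo(float).tiny, True
    t, p = stats.ttest_1samp(v, 0.0)
    return float(t), float(p), bool(p < alpha)


def test_betas(
    roi_betas: pd.DataFrame, alpha: float = 0.0025, value_col: str = "beta"
) -> pd.DataFrame:
    """Bonferroni-style fixed-alpha significance of session-level betas.

    One test per (model, roi, chroma, condition) group across sessions;
    ``alpha`` is the already-corrected level (0.0025 by default).
    """
    group_cols = [
        c for c in ("model", "roi", "chroma", "condition") if c in roi_betas.columns
    ]
    rows = []
    for key, g in roi_betas.groupby(group_cols, sort=True):
        t, p, sig = one_sample_test(g[value_col].to_numpy(), alpha)
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update({"t": t, "p": p, "significant": sig, "n": len(g)})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_model_rmse(rmse_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired t-tests of session-level RMSE between models.

    Expects columns ``model, session, rmse`` plus grouping columns
    ``roi, chroma``; within each roi/chroma, all model pairs are compared
    on paired sessions with Holm-adjusted p-values.
    """
    for col in ("model", "session", "rmse"):
        if col not in rmse_table.columns:
            raise InvalidInputError(f"missing column {col!r}")
    if rmse_table["session"].nunique() < 2:
        raise InvalidInputError("paired comparison needs at least two sessions")
    group_cols = [c for c in ("roi", "chroma") if c in rmse_table.columns]
    results = []
    grouped = rmse_table.groupby(group_cols, sort=True) if group_cols else [((), rmse_table)]
    for key, g in grouped:
        models = sorted(g["model"].unique())
        wide = g.pivot_table(index="session", columns="model", values="rmse")
        rows = []
        for a, b in combinations(models, 2):
            pair = wide[[a, b]].dropna()
            diff = pair[a] - pair[b]
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(pair[a], pair[b])
            row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            row.update(
                {
                    "model_a": a,
                    "model_b": b,
                    "mean_diff": float(diff.mean()),
                    "t": float(t),
                    "p": float(p),
                    "n_sessions": len(pair),
                }
            )
            rows.append(row)
        pvals = [r["p"] for r in rows]
        if pvals:
            reject, p_holm, _, _ = multipletests(pvals, alpha=0.05, method="holm")
            for row, ph, rej in zip(rows, p_holm, reject):
                row["p_holm"] = float(ph)
                row["significant"] = bool(rej)
                row["direction"] = (
                    "a<b" if row["mean_diff"] < 0 else ("a>b" if row["mean_diff"] > 0 else "=")
                )
        results.extend(rows)
    return pd.DataFrame(results)
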