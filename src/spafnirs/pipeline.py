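"""End-to-end model comparison across sessions.

Per session: preprocess (GLM path and block-averaging path), condition
physiology, search per-channel lags, extract tCCA components, fit all six
correction models, and aggregate channel betas to ROIs.  Across sessions:
block averages pooled over trials, beta significance tests, pairwise RMSE
comparisons, session variances, and ICC(3,k) per model and chromophore.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blockavg import EvokedResponse, compute_prq, pooled_average
from .containers import CHROMA, EventSchedule, PhysioRecord, RawScan
from .denoise import regress_out
from .errors import SpaFnirsError
from .glm import (
    MODELS,
    DesignMatrix,
    GlmResult,
    build_design_matrix,
    compare_model_rmse,
    fit_ols,
    roi_weighted_average,
    test_betas,
)
from .physio import (
    ConditionedRegressor,
    LagConfig,
    TccaConfig,
    condition_physio,
    delay_samples,
    find_optimal_lags,
    tcca_select_components,
)
from .preprocess import PreprocessConfig, blockavg_path, glm_path
from .reliability import icc_3k, ratings_matrix, session_variance_table
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)

#: nuisance groups subtracted per model in the denoising comparison
DENOISE_GROUPS = {
    "physio": ("physio",),
    "ss": ("ss",),
    "ss_physio": ("physio", "ss"),
    "ss_physio_lag": ("lag_physio", "ss"),
    "ss_tcca": ("tcca", "ss"),
}


@dataclass
class PipelineConfig:
    """Configuration for one full comparison run."""

    mode: str = "synthetic"  # or "snirf-dir"
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lag: LagConfig = field(default_factory=LagConfig)
    tcca: TccaConfig = field(default_factory=TccaConfig)
    models: tuple[str, ...] = MODELS
    alpha: float = 0.0025
    epoch_window: tuple[float, float] = (-1.0, 15.0)
    compute_block_averages: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "snirf-dir"):
            raise SpaFnirsError(f"unknown input mode {self.mode!r}")
        if self.mode == "snirf-dir" and not self.input_dir:
            raise SpaFnirsError("snirf-dir mode requires input_dir")
        self.simulation.seed = self.seed

    def hash(self) -> str:
        def default(o):
            if is_dataclass(o):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SessionFit:
    """Per-session artifacts from the model comparison."""

    session: int
    channel_betas: pd.DataFrame
    lag_table: pd.DataFrame
    tcca_rho: np.ndarray
    tcca_selected: np.ndarray
    sci: np.ndarray
    denoise_summary: pd.DataFrame
    blockavg_roi: np.ndarray | None  # (n_rois, 2, n_times) at native rate
    blockavg_rois: list[str] | None
    schedule: EventSchedule
    native_rate: float


@dataclass
class ComparisonResult:
    channel_betas: pd.DataFrame
    roi_betas: pd.DataFrame
    icc: pd.DataFrame
    session_variances: pd.DataFrame
    rmse_comparisons: pd.DataFrame
    significance: pd.DataFrame
    lag_table: pd.DataFrame
    mean_lags: pd.DataFrame
    denoise_summary: pd.DataFrame
    evoked: EvokedResponse | None
    evoked_rois: list[str] | None
    physio_evoked: EvokedResponse | None
    failures: list[dict]
    manifest: dict


def _series_layout(hemo) -> pd.DataFrame:
    """Flatten long channels x chroma into a series table."""
    rows = []
    long_idx = np.flatnonzero(hemo.long_mask)
    for ci, ch in enumerate(long_idx):
        for ki, chroma in enumerate(CHROMA):
            rows.append(
                {
                    "series": 2 * ci + ki,
                    "channel": hemo.channel_table.loc[ch, "name"],
                    "roi": hemo.channel_table.loc[ch, "roi"],
                    "chroma": chroma,
                }
            )
    return pd.DataFrame(rows)


def _stack_series(hemo) -> np.ndarray:
    """(n_long * 2, n_times) matrix matching :func:`_series_layout`."""
    long = hemo.concentration[hemo.long_mask]
    return long.reshape(long.shape[0] * 2, long.shape[2])


def _collect_channel_rows(
    fit: GlmResult, layout: pd.DataFrame, model: str, session: int
) -> list[dict]:
    rows = []
    for condition in ("speech", "control"):
        beta = fit.coef(condition)
        se = fit.coef_se(condition)
        for i, rec in layout.iterrows():
            rows.append(
                {
                    "session": session,
                    "model": model,
                    "channel": rec["channel"],
                    "roi": rec["roi"],
                    "chroma": rec["chroma"],
                    "condition": condition,
                    "beta": float(beta[i]),
                    "se": float(se[i]),
                    "rmse": float(fit.rmse[i]),
                }
            )
    return rows


def process_session(
    raw: RawScan,
    physio: PhysioRecord,
    schedule: EventSchedule,
    config: PipelineConfig,
    session: int = 0,
) -> SessionFit:
    """Run preprocessing, all requested models, and denoising for one session."""
    pre = config.preprocess
    hemo, sci = glm_path(raw, pre)
    layout = _series_layout(hemo)
    Y = _stack_series(hemo)
    times = hemo.times
    n_times = hemo.n_times
    rate = hemo.sample_rate

    regressors = condition_physio(physio, times, analysis_rate=rate)
    physio_cols = {name: reg.values for name, reg in regressors.items()}

    short = hemo.concentration[hemo.short_mask]
    short_cols = None
    if short.shape[0]:
        short_cols = {
            "ss_hbo": short[:, 0, :].mean(axis=0),
            "ss_hbr": short[:, 1, :].mean(axis=0),
        }

    # per-series optimal lags for every physiology signal
    lag_rows = []
    lags_by_signal: dict[str, np.ndarray] = {}
    if "ss_physio_lag" in config.models:
        for name, reg in regressors.items():
            lags, corrs = find_optimal_lags(reg, Y, config.lag, rate)
            lags_by_signal[name] = lags
            for i, rec in layout.iterrows():
                lag_rows.append(
                    {
                        "session": session,
                        "signal": name,
                        "channel": rec["channel"],
                        "chroma": rec["chroma"],
                        "lag": float(lags[i]),
                        "corr": float(corrs[i]),
                    }
                )
    lag_table = pd.DataFrame(lag_rows)

    tcca_rho = np.array([])
    tcca_selected = np.array([], dtype=int)
    tcca_cols: dict[str, np.ndarray] = {}
    if "ss_tcca" in config.models:
        tcca_regs = condition_physio(
            physio, times, analysis_rate=rate,
            prefilter_cutoff=config.tcca.prefilter_cutoff,
        )
        tres = tcca_select_components(tcca_regs, Y, config.tcca, rate)
        tcca_rho = tres.rho
        tcca_selected = tres.selected
        tcca_cols = {
            name: tres.components[:, j] for j, name in enumerate(tres.column_names)
        }

    channel_rows: list[dict] = []
    fits: dict[str, tuple[GlmResult, DesignMatrix | list[DesignMatrix]]] = {}
    for model in config.models:
        if model == "ss_physio_lag":
            betas, ses, rmses = [], [], []
            designs = []
            for i in range(Y.shape[0]):
                lagged = {
                    f"{name}_lag": delay_samples(
                        regressors[name].values,
                        int(round(lags_by_signal[name][i] * rate)),
                    )
                    for name in regressors
                }
                X = build_design_matrix(
                    model, schedule, n_times, rate,
                    hrf_params=config.simulation.hrf_params,
                    boxcar_width=config.simulation.boxcar_width,
                    short_channels=short_cols,
                    lagged_physio=lagged,
                )
                f = fit_ols(Y[i], X)
                betas.append(f.beta[0])
                ses.append(f.se[0])
                rmses.append(f.rmse[0])
                designs.append(X)
            fit = GlmResult(
                beta=np.array(betas), se=np.array(ses), rmse=np.array(rmses),
                dof=f.dof, columns=X.columns, model=model,
            )
            fits[model] = (fit, designs)
        else:
            X = build_design_matrix(
                model, schedule, n_times, rate,
                hrf_params=config.simulation.hrf_params,
                boxcar_width=config.simulation.boxcar_width,
                physio_regressors=physio_cols if "physio" in model else None,
                short_channels=short_cols if "ss" in model else None,
                tcca_components=tcca_cols if model == "ss_tcca" else None,
            )
            fit = fit_ols(Y, X)
            fits[model] = (fit, X)
        channel_rows.extend(_collect_channel_rows(fit, layout, model, session))

    # denoising summary: variance before/after nuisance subtraction
    denoise_rows = []
    raw_var = float(np.mean(Y.var(axis=1)))
    for model, groups in DENOISE_GROUPS.items():
        if model not in fits:
            continue
        fit, X = fits[model]
        if model == "ss_tcca" and not tcca_cols:
            groups = ("ss",)  # no components survived the threshold
        if isinstance(X, list):
            variances = []
            for i, Xi in enumerate(X):
                sub = GlmResult(
                    beta=fit.beta[i : i + 1], se=fit.se[i : i + 1],
                    rmse=fit.rmse[i : i + 1], dof=fit.dof,
                    columns=fit.columns, model=fit.model,
                )
                d = regress_out(Y[i], sub, Xi, groups)
                variances.append(d.values.var())
            filtered_var = float(np.mean(variances))
        else:
            d = regress_out(Y, fit, X, groups)
            filtered_var = float(np.mean(d.values.var(axis=1)))
        denoise_rows.append(
            {
                "session": session,
                "model": model,
                "raw_variance": raw_var,
                "filtered_variance": filtered_var,
                "removed": "+".join(groups),
            }
        )
    denoise_summary = pd.DataFrame(denoise_rows)

    blockavg_roi = None
    roi_names = None
    if config.compute_block_averages:
        bhemo, _ = blockavg_path(raw, pre)
        roi_names = [r for r in dict.fromkeys(bhemo.channel_table["roi"]) if r != "scalp"]
        roi_series = np.stack(
            [
                bhemo.concentration[
                    (bhemo.channel_table["roi"] == roi).to_numpy()
                ].mean(axis=0)
                for roi in roi_names
            ]
        )
        blockavg_roi = roi_series

    return SessionFit(
        session=session,
        channel_betas=pd.DataFrame(channel_rows),
        lag_table=lag_table,
        tcca_rho=tcca_rho,
        tcca_selected=tcca_selected,
        sci=sci,
        denoise_summary=denoise_summary,
        blockavg_roi=blockavg_roi,
        blockavg_rois=roi_names,
        schedule=schedule,
        native_rate=raw.sample_rate,
    )


def _load_sessions(config: PipelineConfig):
    if config.mode == "synthetic":
        bundles, _ = generate_dataset(config.simulation)
        for b in bundles:
            yield b.session_index, b.raw, b.physio, b.schedule
    else:
        from . import io as _io

        entries = _io.discover_sessions(config.input_dir)
        if not entries:
            raise SpaFnirsError(f"no session bundles found in {config.input_dir}")
        for i, entry in enumerate(entries):
            raw, physio, schedule = _io.read_session(entry)
            yield i, raw, physio, schedule


def run_model_comparison(config: PipelineConfig) -> ComparisonResult:
    """Run the full six-model comparison across all sessions."""
    session_fits: list[SessionFit] = []
    physio_sessions = []
    failures: list[dict] = []
    for idx, raw, physio, schedule in _load_sessions(config):
        try:
            session_fits.append(process_session(raw, physio, schedule, config, idx))
            physio_sessions.append((physio, schedule))
        except SpaFnirsError as err:
            logger.error("session %d failed: %s", idx, err)
            failures.append({"session": idx, "error": str(err)})
    if not session_fits:
        raise SpaFnirsError("every session failed")

    channel_betas = pd.concat([s.channel_betas for s in session_fits], ignore_index=True)
    roi_betas = roi_weighted_average(channel_betas)

    icc_rows = []
    for model in config.models:
        for chroma in CHROMA:
            try:
                ratings = ratings_matrix(roi_betas, model, chroma)
                res = icc_3k(ratings)
                icc_rows.append(
                    {
                        "model": model,
                        "chroma": chroma,
                        "icc": res.icc,
                        "band": res.band,
                        "F": res.F,
                        "df1": res.df1,
                        "df2": res.df2,
                        "p": res.p,
                    }
                )
            except SpaFnirsError as err:
                icc_rows.append(
                    {"model": model, "chroma": chroma, "icc": np.nan, "band": None,
                     "F": np.nan, "df1": 0, "df2": 0, "p": np.nan, "note": str(err)}
                )
    icc = pd.DataFrame(icc_rows)

    variances = session_variance_table(roi_betas[roi_betas["condition"] == "speech"])
    rmse_table = roi_betas[roi_betas["condition"] == "speech"][
        ["session", "model", "roi", "chroma", "rmse"]
    ]
    comparisons = (
        compare_model_rmse(rmse_table)
        if roi_betas["session"].nunique() > 1 and len(config.models) > 1
        else pd.DataFrame()
    )
    significance = test_betas(roi_betas, alpha=config.alpha)

    lag_table = pd.concat(
        [s.lag_table for s in session_fits if not s.lag_table.empty],
        ignore_index=True,
    ) if any(not s.lag_table.empty for s in session_fits) else pd.DataFrame()
    mean_lags = (
        lag_table.groupby("signal")["lag"].agg(["mean", "std", "count"]).reset_index()
        if not lag_table.empty
        else pd.DataFrame()
    )

    denoise_summary = pd.concat(
        [s.denoise_summary for s in session_fits], ignore_index=True
    )

    evoked = None
    evoked_rois = None
    physio_evoked = None
    with_block = [s for s in session_fits if s.blockavg_roi is not None]
    if with_block:
        evoked_rois = with_block[0].blockavg_rois
        evoked = pooled_average(
            [(s.blockavg_roi, s.native_rate, s.schedule) for s in with_block],
            window=config.epoch_window,
        )
        # physiology block averages share the epoching engine, unfiltered
        rate = with_block[0].native_rate
        physio_stack = []
        for (physio, schedule), s in zip(physio_sessions, session_fits):
            n_raw = int(round(physio.duration * rate))
            sigs = []
            from .simulate import resampled_zscore  # anti-aliased resample

            for name in ("heart_rate", "respiration", "spo2", "ppg", "gsr",
                         "temperature"):
                x = physio.signals[name]
                y = resampled_zscore(x, physio.sample_rate, rate, n_raw)
                sigs.append(y)
            prq = compute_prq(physio.signals["heart_rate"], physio.signals["respiration"])
            sigs.append(resampled_zscore(prq, physio.sample_rate, rate, n_raw))
            physio_stack.append((np.stack(sigs), rate, s.schedule))
        physio_evoked = pooled_average(physio_stack, window=config.epoch_window)

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "models": list(config.models),
        "n_sessions": len(session_fits),
        "n_failures": len(failures),
        "schema_version": "1",
    }
    return ComparisonResult(
        channel_betas=channel_betas,
        roi_betas=roi_betas,
        icc=icc,
        session_variances=variances,
        rmse_comparisons=comparisons,
        significance=significance,
        lag_table=lag_table,
        mean_lags=mean_lags,
        denoise_summary=denoise_summary,
        evoked=evoked,
        evoked_rois=evoked_rois,
        physio_evoked=physio_evoked,
        failures=failures,
        manifest=manifest,
    )


def write_outputs(result: ComparisonResult, outdir) -> dict:
    """Write TSV/JSON artifacts and a manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    tables = {
        "channel_betas.tsv": result.channel_betas,
        "roi_betas.tsv": result.roi_betas,
        "icc.tsv": result.icc,
        "session_variances.tsv": result.session_variances,
        "rmse_comparisons.tsv": result.rmse_comparisons,
        "significance.tsv": result.significance,
        "lag_table.tsv": result.lag_table,
        "mean_lags.tsv": result.mean_lags,
        "denoise_summary.tsv": result.denoise_summary,
    }
    for name, frame in tables.items():
        if frame is None or (hasattr(frame, "empty") and frame.empty):
            continue
        frame.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
        artifacts[name] = name
    if result.evoked is not None:
        rows = []
        for condition, mean in result.evoked.mean.items():
            ci = result.evoked.ci95[condition]
            for ri, roi in enumerate(result.evoked_rois):
                for ki, chroma in enumerate(CHROMA):
                    for ti, t in enumerate(result.evoked.epoch_times):
                        rows.append(
                            {
                                "condition": condition,
                                "roi": roi,
                                "chroma": chroma,
                                "time_s": float(t),
                                "mean": float(mean[ri, ki, ti]),
                                "ci95": float(ci[ri, ki, ti]),
                            }
                        )
        pd.DataFrame(rows).to_csv(
            outdir / "evoked.tsv", sep="\t", index=False, float_format="%.6g"
        )
        artifacts["evoked.tsv"] = "evoked.tsv"
    manifest = dict(result.manifest)
    manifest["artifacts"] = artifacts
    manifest["failures"] = result.failures
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
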