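"""Design construction, OLS estimates, ROI aggregation, and tests on betas."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import gamma as gamma_dist

from spafnirs.containers import EventSchedule
from spafnirs.errors import InvalidInputError, RankDeficiencyError
from spafnirs.glm import (
    DesignMatrix,
    build_design_matrix,
    compare_model_rmse,
    fit_ols,
    one_sample_test,
    roi_weighted_average,
)
from spafnirs.glm import test_betas as beta_significance
from spafnirs.hrf import HrfParams, stimulus_kernel


def simple_schedule():
    return EventSchedule(
        onset=np.array([20.0, 60.0, 100.0, 140.0]),
        duration=np.array([6.0, 6.0, 6.0, 6.0]),
        condition=np.array(["speech", "control", "speech", "control"], dtype=object),
    )


def design(model="none", n_times=120, rate=0.6, **kwargs):
    return build_design_matrix(model, simple_schedule(), n_times, rate, **kwargs)


class TestDesignMatrix:
    def test_none_model_has_three_columns(self):
        X = design("none")
        assert X.columns == ["speech", "control", "intercept"]

    def test_physio_model_adds_exactly_six_columns(self, rng):
        physio = {f"sig{i}": rng.standard_normal(120) for i in range(6)}
        X = design("physio", physio_regressors=physio)
        assert len(X.columns) == len(design("none").columns) + 6

    def test_boxcar_convolution_matches_direct_oracle(self):
        # one isolated event; compare against an explicitly coded
        # double-gamma x boxcar convolution
        rate, n = 2.0, 400
        sched = EventSchedule(
            onset=np.array([50.0]), duration=np.array([6.0]),
            condition=np.array(["speech"], dtype=object),
        )
        X = build_design_matrix("none", sched, n, rate)
        p = HrfParams()
        t = np.arange(0.0, p.duration + 3.0, 1.0 / rate)
        h = (
            gamma_dist.pdf(t, p.peak_delay, scale=1.0)
            - gamma_dist.pdf(t, p.undershoot_delay, scale=1.0) / p.ratio
        )
        kernel = np.convolve(h, np.ones(int(3.0 * rate)))[: len(t)] / rate
        kernel /= np.abs(kernel).max()
        expected = np.zeros(n)
        i0 = int(round(50.0 * rate))
        expected[i0 : i0 + len(kernel)] = kernel[: n - i0]
        np.testing.assert_allclose(X.data["speech"].to_numpy(), expected, atol=1e-10)

    def test_ss_model_without_short_channels_errors(self):
        with pytest.raises(InvalidInputError, match="short"):
            design("ss", short_channels=None)

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidInputError):
            design("fancy")

    def test_duplicate_columns_rejected(self, rng):
        data = pd.DataFrame(
            np.ones((10, 2)), columns=["a", "a"]
        )
        with pytest.raises(InvalidInputError):
            DesignMatrix(data=data, groups={"a": "physio"}, model="physio")


class TestFitOls:
    def test_noiseless_system_recovered_exactly(self, rng):
        X = design("none")
        beta_true = np.array([2.0, -1.0, 0.5])
        y = X.values @ beta_true
        fit = fit_ols(y, X)
        np.testing.assert_allclose(fit.beta[0], beta_true, atol=1e-10)
        assert fit.rmse[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(20):
            n, p = 50, 4
            Xv = rng.standard_normal((n, p - 1))
            data = pd.DataFrame(Xv, columns=["a", "b", "c"])
            data["intercept"] = 1.0
            X = DesignMatrix(
                data=data,
                groups={"a": "physio", "b": "physio", "c": "physio",
                        "intercept": "intercept"},
                model="physio",
            )
            y = rng.standard_normal(n)
            fit = fit_ols(y, X)
            ref = sm.OLS(y, X.values).fit()
            np.testing.assert_allclose(fit.beta[0], ref.params, rtol=1e-10)
            np.testing.assert_allclose(fit.se[0], ref.bse, rtol=1e-10)
            assert fit.rmse[0] == pytest.approx(np.sqrt(ref.ssr / n), rel=1e-10)
            assert fit.dof == int(ref.df_resid)

    def test_rmse_squared_times_n_is_rss(self, rng):
        X = design("none")
        y = rng.standard_normal((3, 120))
        fit = fit_ols(y, X)
        resid = y - fit.beta @ X.values.T
        np.testing.assert_allclose(fit.rmse**2 * 120, np.sum(resid**2, axis=1),
                                   rtol=1e-10)

    def test_orthogonal_nuisance_leaves_stimulus_beta_unchanged(self, rng):
        X = design("none")
        y = rng.standard_normal(120)
        base = fit_ols(y, X)
        z = rng.standard_normal(120)
        A = np.column_stack([X.values, y])
        z -= A @ np.linalg.lstsq(A, z, rcond=None)[0]  # z _|_ X and y
        data = X.data.copy()
        data.insert(2, "nuisance", z)
        X2 = DesignMatrix(
            data=data,
            groups={**X.groups, "nuisance": "physio"},
            model="physio",
        )
        fit2 = fit_ols(y, X2)
        assert fit2.coef("speech")[0] == pytest.approx(base.coef("speech")[0],
                                                       abs=1e-10)

    def test_nested_model_never_increases_rss(self, rng):
        y = rng.standard_normal((4, 120))
        small = fit_ols(y, design("none"))
        physio = {f"sig{i}": rng.standard_normal(120) for i in range(6)}
        big = fit_ols(y, design("physio", physio_regressors=physio))
        assert np.all(big.rmse <= small.rmse + 1e-12)

    def test_collinear_design_raises_with_names(self, rng):
        data = pd.DataFrame(
            {"a": rng.standard_normal(30), "intercept": np.ones(30)}
        )
        data["b"] = 2.0 * data["a"]
        X = DesignMatrix(
            data=data[["a", "b", "intercept"]],
            groups={"a": "physio", "b": "physio", "intercept": "intercept"},
            model="physio",
        )
        with pytest.raises(RankDeficiencyError):
            fit_ols(rng.standard_normal(30), X)


class TestRoiAggregation:
    def frame(self, betas, ses):
        return pd.DataFrame(
            {
                "roi": ["r"] * len(betas),
                "chroma": ["hbo"] * len(betas),
                "condition": ["speech"] * len(betas),
                "beta": betas,
                "se": ses,
            }
        )

    def test_equal_se_reduces_to_mean(self):
        out = roi_weighted_average(self.frame([1.0, 2.0, 6.0], [0.5, 0.5, 0.5]))
        assert out["beta"].iloc[0] == pytest.approx(3.0)

    def test_inverse_se_weights_formula(self):
        out = roi_weighted_average(self.frame([2.0, 4.0], [1.0, 2.0]))
        assert out["beta"].iloc[0] == pytest.approx(8.0 / 3.0)

    def test_single_channel_roi_passthrough(self):
        out = roi_weighted_average(self.frame([3.14], [0.2]))
        assert out["beta"].iloc[0] == pytest.approx(3.14)


class TestBetaTests:
    def test_all_zero_not_significant(self):
        t, p, sig = one_sample_test(np.zeros(10))
        assert not sig and p == 1.0

    def test_zero_variance_nonzero_mean_flagged(self):
        t, p, sig = one_sample_test(np.full(5, 2.0))
        assert sig and p <= np.finfo(float).tiny

    def test_t_statistic_matches_hand_formula(self):
        v = np.array([0.3, 0.5, 0.1, 0.4, 0.2])
        t, p, _ = one_sample_test(v)
        expected = v.mean() / (v.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected, rel=1e-12)

    def test_grouped_frame_interface(self, rng):
        frame = pd.DataFrame(
            {
                "model": ["none"] * 10 + ["ss"] * 10,
                "roi": ["r"] * 20,
                "chroma": ["hbo"] * 20,
                "condition": ["speech"] * 20,
                "beta": np.r_[rng.normal(5, 0.1, 10), rng.normal(0, 1, 10)],
            }
        )
        out = beta_significance(frame, alpha=0.0025)
        assert len(out) == 2
        assert bool(out.loc[out["model"] == "none", "significant"].iloc[0])


class TestRmseComparison:
    def make_table(self, rng, n_models=6, n_sessions=8, offsets=None):
        rows = []
        offsets = offsets or {}
        for m in range(n_models):
            name = f"m{m}"
            base = rng.normal(1.0, 0.02, n_sessions) + offsets.get(name, 0.0)
            for s, v in enumerate(base):
                rows.append({"model": name, "session": s, "roi": "r",
                             "chroma": "hbo", "rmse": v})
        return pd.DataFrame(rows)

    def test_identical_models_not_significant(self, rng):
        table = self.make_table(rng, n_models=1)
        dup = table.assign(model="m1")
        out = compare_model_rmse(pd.concat([table, dup], ignore_index=True))
        assert len(out) == 1
        assert out["mean_diff"].iloc[0] == pytest.approx(0.0)
        assert not out["significant"].iloc[0]

    def test_six_models_give_fifteen_pairs(self, rng):
        out = compare_model_rmse(self.make_table(rng))
        assert len(out) == 15

    def test_clear_separation_detected(self, rng):
        table = self.make_table(rng, n_models=2, offsets={"m1": 0.5})
        out = compare_model_rmse(table)
        assert out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "a<b"  # m0 lower RMSE than m1

    def test_single_session_rejected(self):
        table = pd.DataFrame(
            {"model": ["a", "b"], "session": [0, 0], "rmse": [1.0, 2.0]}
        )
        with pytest.raises(InvalidInputError):
            compare_model_rmse(table)
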