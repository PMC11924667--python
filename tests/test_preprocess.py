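"""Preprocessing stages against analytic cases and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.stats import pearsonr

from spafnirs.containers import RawScan
from spafnirs.errors import InvalidInputError
from spafnirs.preprocess import (
    PreprocessConfig,
    _sci_filter,
    bandpass_and_resample,
    extinction_matrix,
    forward_mbll,
    glm_path,
    intensity_to_od,
    od_to_hemoglobin,
    scalp_coupling_index,
    short_channel_subtract,
    tddr,
)
from spafnirs.simulate import generate_session
from conftest import small_config


def make_scan(intensity, rate=5.1, is_short=None):
    n_ch = intensity.shape[0]
    is_short = is_short or [False] * n_ch
    table = pd.DataFrame(
        {
            "name": [f"S{i}_D{i}" for i in range(n_ch)],
            "source": range(1, n_ch + 1),
            "detector": range(1, n_ch + 1),
            "separation_mm": [8.0 if s else 30.0 for s in is_short],
            "is_short": is_short,
            "roi": ["roi_a"] * n_ch,
        }
    )
    return RawScan(
        intensity=intensity, sample_rate=rate, wavelengths=(760.0, 850.0),
        channel_table=table,
    )


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        scan = make_scan(np.full((2, 2, 100), 3.7))
        assert np.allclose(intensity_to_od(scan), 0.0)

    def test_half_mean_sample_gives_ln2(self):
        # 600 samples at 1.0 except one at x chosen so that mean I = 2x
        intensity = np.ones((1, 2, 600))
        x = 599.0 / 1199.0  # then mean = (599 + x)/600 = 2x
        intensity[0, :, 0] = x
        od = intensity_to_od(scan := make_scan(intensity))
        assert od[0, 0, 0] == pytest.approx(np.log(2.0), rel=1e-12)

    def test_matches_elementwise_log_oracle(self, rng):
        intensity = rng.uniform(0.5, 2.0, (3, 2, 200))
        od = intensity_to_od(make_scan(intensity))
        expected = -np.log(intensity / intensity.mean(axis=2, keepdims=True))
        np.testing.assert_allclose(od, expected, rtol=1e-12)

    def test_nonpositive_intensity_names_channel(self):
        intensity = np.ones((2, 2, 50))
        intensity[1, 0, 7] = 0.0
        with pytest.raises(InvalidInputError, match="S1_D1"):
            intensity_to_od(make_scan(intensity))


class TestScalpCouplingIndex:
    def make_od(self, a, b):
        return np.stack([np.stack([a, b])])

    def test_identical_wavelengths_sci_one(self, rng):
        x = rng.standard_normal(2000)
        sci, keep = scalp_coupling_index(self.make_od(x, x), 5.1)
        assert sci[0] == pytest.approx(1.0)
        assert keep[0]

    def test_sign_flipped_dropped(self, rng):
        x = rng.standard_normal(2000)
        sci, keep = scalp_coupling_index(self.make_od(x, -x), 5.1)
        assert sci[0] == pytest.approx(-1.0)
        assert not keep[0]

    def test_matches_filtered_pearson_oracle(self, rng):
        t = np.arange(3000) / 5.1
        shared = np.sin(2 * np.pi * 1.4 * t)
        a = shared + 0.5 * rng.standard_normal(len(t))
        b = shared + 0.5 * rng.standard_normal(len(t))
        sci, _ = scalp_coupling_index(self.make_od(a, b), 5.1)
        taps = _sci_filter(5.1, 1.35, 0.1)
        fa = sps.filtfilt(taps, [1.0], a)
        fb = sps.filtfilt(taps, [1.0], b)
        assert sci[0] == pytest.approx(pearsonr(fa, fb).statistic, abs=1e-10)

    def test_too_short_series_raises(self):
        with pytest.raises(InvalidInputError):
            scalp_coupling_index(np.ones((1, 2, 50)), 5.1)


class TestTddr:
    def test_smooth_sinusoid_shape_preserved(self):
        # the biweight mildly shrinks the derivative tails of a clean
        # oscillation, so "unchanged" means shape-preserving within the
        # shrinkage the published algorithm itself applies
        t = np.arange(2000) / 5.1
        x = np.sin(2 * np.pi * 0.05 * t)
        y = tddr(x[None, :], 5.1)[0]
        assert np.abs(y - x).max() < 0.3
        assert np.corrcoef(x, y)[0, 1] > 0.98

    def test_zero_and_constant_series_pass_through(self):
        assert np.allclose(tddr(np.zeros((1, 100)), 5.1), 0.0)
        assert np.allclose(tddr(np.full((1, 100), 2.5), 5.1), 2.5)

    def test_step_artifact_suppressed(self, rng):
        t = np.arange(3000) / 5.1
        clean = np.sin(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal(len(t))
        artifact = np.where(t > t[len(t) // 2], 10.0 * clean.std(), 0.0)
        repaired = tddr((clean + artifact)[None, :], 5.1)[0]
        step_before = artifact[-1]
        step_after = abs(
            repaired[len(t) // 2 + 50 :].mean() - repaired[: len(t) // 2 - 50].mean()
        )
        assert step_after < 0.2 * step_before

    def test_matches_reference_implementation(self, rng):
        # mne's array-level TDDR is an independent implementation of the
        # same published robust-reweighting algorithm
        from mne.preprocessing.nirs._tddr import _TDDR

        for _ in range(5):
            x = np.cumsum(rng.standard_normal(800)) * 0.1
            x[400:] += 5.0
            ours = tddr(x[None, :], 5.1)[0]
            theirs = _TDDR(x.copy(), 5.1)
            np.testing.assert_allclose(ours, theirs, rtol=1e-6, atol=1e-9)


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        table = make_scan(np.ones((2, 2, 10))).channel_table
        hemo = od_to_hemoglobin(np.zeros((2, 2, 10)), table, sample_rate=5.1)
        assert np.allclose(hemo.concentration, 0.0)

    def test_forward_inverse_round_trip(self, rng):
        conc = rng.normal(0.0, 1.0, (3, 2, 50))
        seps_cm = np.array([3.0, 3.0, 0.8])
        od = forward_mbll(conc, seps_cm, ppf=0.1)
        table = make_scan(
            np.ones((3, 2, 50)), is_short=[False, False, True]
        ).channel_table
        hemo = od_to_hemoglobin(od, table, sample_rate=5.1)
        np.testing.assert_allclose(hemo.concentration, conc, rtol=1e-10)

    def test_explicit_2x2_solve_oracle(self, rng):
        od = rng.normal(0.0, 0.01, (1, 2, 20))
        table = make_scan(np.ones((1, 2, 20))).channel_table
        hemo = od_to_hemoglobin(od, table, sample_rate=5.1)
        e = extinction_matrix((760.0, 850.0))
        for ti in range(20):
            expected = np.linalg.solve(e, od[0, :, ti] / (3.0 * 0.1)) * 1e6
            np.testing.assert_allclose(hemo.concentration[0, :, ti], expected,
                                       rtol=1e-10)

    def test_doubling_ppf_halves_concentration(self, rng):
        od = rng.normal(0.0, 0.01, (1, 2, 30))
        table = make_scan(np.ones((1, 2, 30))).channel_table
        c1 = od_to_hemoglobin(od, table, PreprocessConfig(ppf=0.1), 5.1).concentration
        c2 = od_to_hemoglobin(od, table, PreprocessConfig(ppf=0.2), 5.1).concentration
        np.testing.assert_allclose(c1, 2.0 * c2, rtol=1e-12)


class TestFilterResample:
    def make_hemo(self, data, rate=5.1):
        scan = make_scan(np.ones((data.shape[0], 2, data.shape[2])))
        from spafnirs.containers import HemoTimeSeries

        return HemoTimeSeries(
            concentration=data, sample_rate=rate, channel_table=scan.channel_table
        )

    def test_decimation_hits_analysis_rate(self, rng):
        hemo = self.make_hemo(rng.standard_normal((1, 2, 6120)))
        out = bandpass_and_resample(hemo, band=None, target_rate=0.6)
        assert out.sample_rate == 0.6
        assert out.n_times == 720

    def test_dc_removed_by_bandpass(self):
        hemo = self.make_hemo(np.full((1, 2, 6120), 5.0))
        out = bandpass_and_resample(hemo, band=(0.02, 0.4), target_rate=None)
        assert abs(out.concentration.mean()) < 1e-6

    def test_passband_amplitude_preserved_fft_oracle(self):
        t = np.arange(8160) / 5.1
        x = np.sin(2 * np.pi * 0.1 * t)
        hemo = self.make_hemo(np.broadcast_to(x, (1, 2, len(t))).copy())
        out = bandpass_and_resample(hemo, band=(0.02, 0.4), target_rate=None)
        spec = np.abs(np.fft.rfft(out.concentration[0, 0])) * 2 / len(t)
        freqs = np.fft.rfftfreq(len(t), 1 / 5.1)
        peak = spec[np.argmin(np.abs(freqs - 0.1))]
        assert abs(peak - 1.0) < 0.05

    def test_band_incompatible_with_target_rate(self, rng):
        hemo = self.make_hemo(rng.standard_normal((1, 2, 6120)))
        with pytest.raises(InvalidInputError):
            bandpass_and_resample(hemo, band=(0.02, 0.4), target_rate=0.6)


class TestShortChannelSubtract:
    def make_hemo(self, long, short):
        data = np.stack([long, short])
        from spafnirs.containers import HemoTimeSeries

        scan = make_scan(np.ones((2, 2, long.shape[1])), is_short=[False, True])
        return HemoTimeSeries(
            concentration=data, sample_rate=5.1, channel_table=scan.channel_table
        )

    def test_exact_scaling_gives_zero_residual(self, rng):
        ref = rng.standard_normal((2, 500))
        hemo = self.make_hemo(2.0 * ref, ref)
        out = short_channel_subtract(hemo)
        assert np.allclose(out.concentration[0], 0.0, atol=1e-10)

    def test_residual_orthogonal_to_reference(self, rng):
        hemo = self.make_hemo(
            rng.standard_normal((2, 500)), rng.standard_normal((2, 500))
        )
        out = short_channel_subtract(hemo)
        for k in range(2):
            ref = hemo.concentration[1, k]
            assert abs(out.concentration[0, k] @ ref) < 1e-8 * len(ref)

    def test_evoked_component_survives_projection_oracle(self, rng):
        ref = rng.standard_normal((2, 800))
        evoked = np.zeros((2, 800))
        evoked[0, 100:200] = 1.0
        hemo = self.make_hemo(ref + evoked, ref)
        out = short_channel_subtract(hemo)
        for k in range(2):
            r = ref[k]
            expected = (ref[k] + evoked[k]) - ((ref[k] + evoked[k]) @ r / (r @ r)) * r
            np.testing.assert_allclose(out.concentration[0, k], expected, atol=1e-10)

    def test_no_short_channels_warns_and_passes_through(self, rng):
        from spafnirs.containers import HemoTimeSeries

        scan = make_scan(np.ones((1, 2, 100)))
        hemo = HemoTimeSeries(
            concentration=rng.standard_normal((1, 2, 100)),
            sample_rate=5.1,
            channel_table=scan.channel_table,
        )
        with pytest.warns(UserWarning):
            out = short_channel_subtract(hemo)
        np.testing.assert_array_equal(out.concentration, hemo.concentration)


class TestGlmPathAudit:
    def test_glm_input_is_unfiltered_resampled_mbll(self):
        """The GLM path must be bit-identical to MBLL + decimation alone."""
        bundle = generate_session(small_config(), 0)
        cfg = PreprocessConfig()
        hemo, sci = glm_path(bundle.raw, cfg)

        od = intensity_to_od(bundle.raw)
        _, keep = scalp_coupling_index(od, bundle.raw.sample_rate, cfg)
        manual = od_to_hemoglobin(od[keep], bundle.raw.select(keep), cfg)
        manual = bandpass_and_resample(manual, band=None, target_rate=0.6)
        np.testing.assert_array_equal(hemo.concentration, manual.concentration)

    def test_pruned_channels_absent_downstream(self, rng):
        bundle = generate_session(small_config(), 0)
        # sabotage one channel with anti-correlated wavelengths
        intensity = bundle.raw.intensity.copy()
        x = rng.standard_normal(intensity.shape[2]) * 0.05
        intensity[2, 0] = np.exp(x) * 1.0
        intensity[2, 1] = np.exp(-x) * 1.0
        scan = RawScan(
            intensity=intensity, sample_rate=bundle.raw.sample_rate,
            wavelengths=bundle.raw.wavelengths, channel_table=bundle.raw.channel_table,
        )
        hemo, sci = glm_path(scan)
        assert sci[2] < 0.7
        assert hemo.n_channels == scan.n_channels - 1
        dropped = scan.channel_table.loc[2, "name"]
        assert dropped not in set(hemo.channel_table["name"])
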