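"""HRF, convolution, modulators, GLM1/GLM2/FIR designs, filtering, collinearity."""

import numpy as np
import pytest

from valuedyn import fmri_design as fd
from valuedyn import task_synth as ts
from valuedyn.errors import InvalidArgumentError

TR = 0.910
HRF = fd.HRFSpec()


class TestGammaHRF:
    def test_peak_within_one_tr_of_requested_delay(self):
        kern = fd.gamma_hrf(HRF, TR)
        assert abs(np.argmax(kern) * TR - HRF.peak_delay_s) <= TR

    def test_kernel_nonnegative_unit_peak(self):
        kern = fd.gamma_hrf(HRF, TR)
        assert np.all(kern >= 0)
        assert kern.max() <= 1.0 + 1e-12

    def test_tail_mass_beyond_32s_is_negligible(self):
        short = fd.gamma_hrf(HRF, TR)
        long = fd.gamma_hrf(fd.HRFSpec(duration_s=64.0), TR)
        # gamma tail bound: extending the window adds almost no mass
        assert abs(long.sum() - short.sum()) * TR < 1e-6 * short.sum() * TR + 1e-6

    def test_invalid_tr(self):
        with pytest.raises(InvalidArgumentError):
            fd.gamma_hrf(HRF, 0.0)


class TestConvolveEvents:
    N = 120

    def test_impulse_proportional_to_hrf(self):
        dt = TR / 10
        reg = fd.convolve_events([0.0], [dt], [1.0], HRF, self.N, TR)
        kern = fd.gamma_hrf(HRF, TR)
        k = len(kern)
        ratio = reg[1:k][kern[1:] > 1e-3] / kern[1:][kern[1:] > 1e-3]
        assert np.allclose(ratio, ratio[0], rtol=1e-6)

    def test_linearity(self):
        both = fd.convolve_events([5.0, 30.0], [4.55, 4.55], [1.0, 1.0],
                                  HRF, self.N, TR)
        a = fd.convolve_events([5.0], [4.55], [1.0], HRF, self.N, TR)
        b = fd.convolve_events([30.0], [4.55], [1.0], HRF, self.N, TR)
        np.testing.assert_allclose(both, a + b, atol=1e-12)

    def test_homogeneity(self):
        one = fd.convolve_events([10.0], [2.73], [1.0], HRF, self.N, TR)
        two = fd.convolve_events([10.0], [2.73], [2.0], HRF, self.N, TR)
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)

    def test_event_beyond_run_end_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fd.convolve_events([self.N * TR + 1], [1.0], [1.0], HRF, self.N, TR)


class TestModulators:
    def test_zscore_closed_form(self):
        out = fd.zscore_modulator([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.224744871, 0.0, 1.224744871])

    def test_zscore_moments_and_idempotence(self, rng):
        v = rng.normal(3, 7, 50)
        z = fd.zscore_modulator(v)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1) < 1e-12
        np.testing.assert_allclose(fd.zscore_modulator(z), z, atol=1e-12)

    def test_zscore_constant_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fd.zscore_modulator([2.0, 2.0, 2.0])

    def test_orthogonalize_projection_property(self, rng):
        t = rng.normal(size=200)
        r = rng.normal(size=200)
        out = fd.orthogonalize(t, r)
        assert abs(out @ r) < 1e-10 * np.linalg.norm(out) * np.linalg.norm(r) + 1e-10
        assert abs(out.sum()) < 1e-8

    def test_orthogonalize_already_orthogonal_unchanged(self):
        n = 100
        t = np.sin(np.arange(n))
        t -= t.mean()
        r = np.ones(n)  # constant reference: projection removes only the mean
        np.testing.assert_allclose(fd.orthogonalize(t, r), t, atol=1e-12)

    def test_orthogonalize_self_gives_zero(self, rng):
        r = rng.normal(size=50)
        np.testing.assert_allclose(fd.orthogonalize(r, r), 0, atol=1e-12)

    def test_orthogonalize_zero_reference_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fd.orthogonalize(np.ones(10), np.zeros(10))


@pytest.fixture(scope="module")
def run_setup(small_session, small_estimates):
    run = 0
    est = small_estimates[small_estimates["run"] == run]
    events = ts.run_events(small_session, small_estimates, run)
    n_scans = ts.n_scans_for_run(small_session, run)
    return est, events, n_scans


class TestGLM1Design:
    def test_seven_named_task_columns(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_glm1_design(est, events, HRF, n_scans, TR)
        assert dm.task_columns() == list(fd.GLM1_COLUMNS)
        assert dm.matrix.shape == (n_scans, 8)  # + constant

    def test_modulators_orthogonal_to_phase_baseline(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_glm1_design(est, events, HRF, n_scans, TR)
        for mod, base in (("sv_offer", "offer"), ("cd_offer", "offer"),
                          ("sv_commit", "commit"), ("cd_commit", "commit")):
            a, b = dm.column(mod), dm.column(base)
            assert abs(a @ b) < 1e-10 * np.linalg.norm(a) * np.linalg.norm(b) + 1e-12

    def test_noiseless_amplitude_recovery(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_glm1_design(est, events, HRF, n_scans, TR)
        truth = {"offer": 2.0, "sv_offer": 1.5, "cd_commit": -0.8, "const": 0.3}
        y = sum(a * dm.column(c) for c, a in truth.items())
        beta, *_ = np.linalg.lstsq(dm.matrix, y, rcond=None)
        for c, a in truth.items():
            assert beta[dm.column_names.index(c)] == pytest.approx(a, abs=1e-8)
        for c in set(dm.column_names) - set(truth):
            assert beta[dm.column_names.index(c)] == pytest.approx(0, abs=1e-8)

    def test_missing_payout_warns_and_omits(self, run_setup):
        est, events, n_scans = run_setup
        ev = events[events["trial_type"] != "payout"]
        with pytest.warns(UserWarning):
            dm = fd.build_glm1_design(est, ev, HRF, n_scans, TR)
        assert "payout" not in dm.column_names


class TestGLM2Design:
    def test_nine_named_task_columns(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_glm2_design(est, events, HRF, n_scans, TR)
        assert len(dm.task_columns()) == 9
        assert dm.task_columns() == list(fd.GLM2_COLUMNS)

    def test_partition_identity_with_glm1_baselines(self, run_setup):
        est, events, n_scans = run_setup
        d1 = fd.build_glm1_design(est, events, HRF, n_scans, TR)
        d2 = fd.build_glm2_design(est, events, HRF, n_scans, TR)
        for phase in ("offer", "commit"):
            summed = sum(d2.column(f"{c}_{phase}")
                         for c in ("AccCon", "AccAmb", "RejCon", "RejAmb"))
            np.testing.assert_allclose(summed, d1.column(phase), atol=1e-10)

    def test_single_condition_signal_loads_only_on_own_column(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_glm2_design(est, events, HRF, n_scans, TR)
        y = 3.0 * dm.column("RejCon_commit")
        beta, *_ = np.linalg.lstsq(dm.matrix, y, rcond=None)
        for i, name in enumerate(dm.column_names):
            expect = 3.0 if name == "RejCon_commit" else 0.0
            assert beta[i] == pytest.approx(expect, abs=1e-7)

    def test_empty_condition_flagged(self, run_setup):
        est, events, n_scans = run_setup
        est2 = est.copy()
        est2.loc[est2["condition"] == "RejAmb", "condition"] = "RejCon"
        dm = fd.build_glm2_design(est2, events, HRF, n_scans, TR)
        assert "RejAmb_offer" in dm.flagged_empty
        assert "RejAmb_commit" in dm.flagged_empty


class TestFIRDesign:
    def test_last_sample_time(self):
        assert (18 - 1) * TR == pytest.approx(15.47)

    def test_column_count_and_names(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_fir_design(est, events, n_scans, TR, n_points=18)
        groups = {n.rsplit("_", 1)[0] for n in dm.task_columns()}
        assert groups == {"offer", "sv", "cd", "payout"}
        assert len(dm.task_columns()) == 4 * 18

    def test_exact_deconvolution_of_nonoverlapping_responses(self):
        # well-spaced scan-aligned impulses carrying a known response shape
        n_scans, n_points = 400, 18
        onsets = np.arange(5, 360, 30) * TR
        shape = np.exp(-0.5 * ((np.arange(n_points) - 6) / 2.5) ** 2)
        y = np.zeros(n_scans)
        for on in onsets:
            k = int(round(on / TR))
            y[k:k + n_points] += shape
        events = {"onset": onsets, "duration": [4.55] * len(onsets),
                  "trial_type": ["offer"] * len(onsets),
                  "offer_id": np.arange(len(onsets))}
        import pandas as pd
        ev = pd.DataFrame(events)
        est = pd.DataFrame({"offer_id": np.arange(len(onsets)),
                            "sv": np.linspace(-2, 2, len(onsets)),
                            "confidence": np.linspace(-2, 2, len(onsets)) ** 2,
                            "in_fmri": True})
        dm = fd.build_fir_design(est, ev, n_scans, TR, n_points=n_points)
        beta, *_ = np.linalg.lstsq(dm.matrix, y, rcond=None)
        got = [beta[dm.column_names.index(f"offer_t{k:02d}")] for k in range(n_points)]
        np.testing.assert_allclose(got, shape, atol=1e-8)

    def test_single_point_fir(self, run_setup):
        est, events, n_scans = run_setup
        dm = fd.build_fir_design(est, events, n_scans, TR, n_points=1)
        col = dm.column("offer_t00")
        onsets = events[events["trial_type"] == "offer"]["onset"]
        scans = np.rint(onsets / TR).astype(int)
        expected = np.zeros(n_scans)
        np.add.at(expected, scans, 1.0)
        np.testing.assert_allclose(col, expected)


class TestHighpassFilter:
    def test_linear_trend_removed(self):
        n = 300
        trend = 5.0 * np.arange(n) / n
        out = fd.highpass_filter(trend, sigma_s=50.0, tr=TR)
        assert np.max(np.abs(out - trend.mean())) < 1e-6 * 5.0

    def test_constant_series_unchanged(self):
        out = fd.highpass_filter(np.full(100, 3.7), sigma_s=50.0, tr=TR)
        np.testing.assert_allclose(out, 3.7, atol=1e-10)

    def test_transfer_function_matches_analytic_gain(self):
        """A Gaussian-weighted running-line fit predicts, at the window
        centre, the Gaussian-smoothed value, so the filter attenuates a
        sinusoid of period T by exp(-2 pi^2 sigma^2 / T^2) -- a closed-form
        oracle for the empirical transfer function.  Slow components are
        attenuated progressively; fast components (20 s) pass nearly
        untouched."""
        n, sigma = 700, 50.0
        t = np.arange(n) * TR
        sl = slice(n // 4, 3 * n // 4)
        for period in (400.0, 300.0, 200.0, 100.0, 20.0):
            x = np.sin(2 * np.pi * t / period)
            out = fd.highpass_filter(x, sigma_s=sigma, tr=TR)
            out = out - out.mean()
            atten = 1.0 - np.std(out[sl]) / np.std(x[sl])
            analytic = np.exp(-2 * np.pi ** 2 * sigma ** 2 / period ** 2)
            assert atten == pytest.approx(analytic, abs=0.02)
        # ordering sanity: slower components are removed more
        assert np.exp(-2 * np.pi ** 2 * sigma ** 2 / 400.0 ** 2) > 0.5
        assert np.exp(-2 * np.pi ** 2 * sigma ** 2 / 20.0 ** 2) < 0.01

    def test_filter_commutes_with_column_stacking(self, rng):
        y = rng.normal(size=(200, 4))
        stacked = fd.highpass_filter(y, sigma_s=50.0, tr=TR)
        separate = np.column_stack([
            fd.highpass_filter(y[:, j], sigma_s=50.0, tr=TR) for j in range(4)])
        np.testing.assert_allclose(stacked, separate, atol=1e-12)


class TestCollinearity:
    def _design(self, cols, names):
        return fd.DesignMatrix(matrix=np.column_stack(cols),
                               column_names=list(names), tr=TR)

    def test_orthogonal_columns_have_unit_vif(self, rng):
        n = 128
        t = np.arange(n)
        a = np.sin(2 * np.pi * t / 16)
        b = np.cos(2 * np.pi * t / 16)
        dm = self._design([a, b], ["a", "b"])
        rep = fd.collinearity_report([dm], pairs=[("a", "b")],
                                     columns_of_interest=["a", "b"])
        assert rep.vif["a"] == pytest.approx(1.0, abs=1e-8)
        assert rep.vif["b"] == pytest.approx(1.0, abs=1e-8)
        assert rep.pairwise_r2[("a", "b")] == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=100)
        dm = self._design([x, x.copy()], ["x", "x_dup"])
        rep = fd.collinearity_report([dm], pairs=[], columns_of_interest=["x"])
        assert "x" in rep.infinite_vif
        assert rep.vif["x"] == fd.VIF_CAP

    def test_vif_matches_direct_regression_oracle(self, rng):
        x = fd.zscore_modulator(rng.normal(size=300))
        x2 = x ** 2
        z = rng.normal(size=300)
        dm = self._design([x, x2, z], ["x", "x_sq", "z"])
        rep = fd.collinearity_report([dm], pairs=[("x", "x_sq")],
                                     columns_of_interest=["x_sq"])
        # brute-force multiple regression of x^2 on {x, z, const}
        X = np.column_stack([x, z, np.ones(300)])
        beta, *_ = np.linalg.lstsq(X, x2, rcond=None)
        resid = x2 - X @ beta
        r2 = 1 - resid @ resid / ((x2 - x2.mean()) @ (x2 - x2.mean()))
        assert rep.vif["x_sq"] == pytest.approx(1 / (1 - r2), abs=1e-8)
        # z-scored Gaussian sample: x and x^2 nearly uncorrelated
        assert rep.pairwise_r2[("x", "x_sq")] < 0.05
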