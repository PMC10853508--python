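"""Signal chain: HRF kernel, detrending, global filter, Hbdiff, GLM betas."""

import numpy as np
import pytest

from nirscv import (
    HRFParams,
    PreprocessOptions,
    canonical_hrf,
    detrend,
    glm_betas,
    hbdiff,
    preprocess_cohort,
    remove_global,
    simulate_cohort,
)
from nirscv.simulate import Cohort

from conftest import compact_config, compact_design


class TestCanonicalHRF:
    def test_peak_time_matches_gamma_mode(self):
        """The double-gamma peak sits at the mode of the peak gamma density,
        (shape - 1) * scale = 5 s for the default 6 s / 1 s parameters."""
        sr = 30.0
        h = canonical_hrf(sr)
        assert abs(np.argmax(h) / sr - 5.0) <= 1.0 / sr + 1e-12

    def test_unit_peak_and_zero_onset(self):
        h = canonical_hrf(10.0)
        assert h.max() == 1.0
        assert h[0] == 0.0

    def test_undershoot_is_negative(self):
        h = canonical_hrf(10.0)
        assert h.min() < 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(0)
        with pytest.raises(ValueError):
            HRFParams(peak_delay=-1)


class TestDetrend:
    FS = 1.0
    N = 512

    def test_linear_ramp_removed(self):
        ramp = np.linspace(0.0, 1.0, self.N)
        out = detrend(ramp, 128, self.FS)
        assert np.abs(out).max() < 0.01

    def test_task_band_sinusoid_preserved(self):
        """A 30-s-period sinusoid (the block frequency) passes a 128-s
        cutoff with amplitude within 5%, measured at its FFT bin."""
        t = np.arange(self.N)
        sin = np.sin(2 * np.pi * t / 30)
        out = detrend(sin, 128, self.FS)
        k = np.argmax(np.abs(np.fft.rfft(sin)))
        ratio = np.abs(np.fft.rfft(out)[k]) / np.abs(np.fft.rfft(sin)[k])
        assert abs(ratio - 1.0) < 0.05

    def test_superposition_recovers_sinusoid(self):
        t = np.arange(self.N)
        sin = np.sin(2 * np.pi * t / 30)
        out = detrend(5.0 * np.linspace(0, 1, self.N) + sin, 128, self.FS)
        rms_err = np.sqrt(np.mean((out - (sin - sin.mean())) ** 2))
        assert rms_err < 0.05 * np.sqrt(np.mean(sin**2))

    def test_output_zero_mean_and_matrix_input(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, self.N)) + np.linspace(0, 4, self.N)
        out = detrend(X, 128, self.FS)
        assert out.shape == X.shape
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detrend(np.zeros(100), 128, 1.0)


class TestRemoveGlobal:
    def test_pure_global_removed(self):
        t = np.arange(400)
        g = np.sin(0.1 * t) + 0.3 * np.cos(0.02 * t)
        X = np.tile(g, (6, 1))
        out = remove_global(X)
        assert np.abs(out).max() < 1e-8 * np.abs(g).max()

    def test_channel_unique_signals_preserved(self):
        """Orthogonal per-channel signals survive removal of a dominant
        shared component to within 10% RMS.

        The estimated global series inevitably absorbs the across-channel
        mean of the unique signals (a 1/sqrt(n_channels) contamination
        inherent to global-signal estimation), so the bound is checked at a
        channel count where that floor sits below 10%.
        """
        n, n_ch = 2048, 128
        t = np.arange(n)
        # exact Fourier bins: shared series and per-channel signals mutually orthogonal
        g = 5.0 * np.sin(2 * np.pi * 1 * t / n)
        uniq = np.array([np.sin(2 * np.pi * (k + 3) * t / n) for k in range(n_ch)])
        X = g[None, :] + uniq
        out = remove_global(X)
        for c in range(n_ch):
            err = np.sqrt(np.mean((out[c] - uniq[c]) ** 2))
            assert err < 0.1 * np.sqrt(np.mean(uniq[c] ** 2))

    def test_zero_matrix_passes_through(self):
        out = remove_global(np.zeros((4, 100)))
        assert (out == 0).all()

    def test_single_channel_and_constant_rejected(self):
        with pytest.raises(ValueError):
            remove_global(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            remove_global(np.full((4, 100), 2.5))

    def test_protected_task_component_survives(self):
        """When all channels share a task-locked response, protection by the
        regressor prevents the filter from deleting it."""
        design = compact_design()
        reg = design.regressor
        amp = np.linspace(0.5, 2.0, 8)
        X = amp[:, None] * reg[None, :]
        out_protected = remove_global(X, protect=reg)
        out_naive = remove_global(X)
        resid_protected = np.abs(out_protected - (X - X.mean(1, keepdims=True))).max()
        assert resid_protected < 1e-8
        # without protection the shared task component is (wrongly) removed
        assert np.abs(out_naive).max() < 0.1 * np.abs(X).max()


class TestHbdiff:
    def test_anticorrelated_doubles(self):
        x = np.arange(12.0).reshape(2, 6)
        np.testing.assert_array_equal(hbdiff(x, -x), 2 * x)

    def test_identical_cancels(self):
        x = np.ones((2, 4))
        assert (hbdiff(x, x) == 0).all()

    def test_linearity_with_ratio(self):
        reg = np.sin(np.arange(50.0))
        a = 2.0
        np.testing.assert_allclose(
            hbdiff(reg * a, reg * (-0.5 * a)), reg * 1.5 * a, atol=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hbdiff(np.zeros((2, 3)), np.zeros((2, 4)))


class TestGLMBetas:
    def test_noiseless_subject_recovers_scaled_amplitude(self, noiseless_config):
        from nirscv import simulate_subject

        design = compact_design()
        amp = np.linspace(0.5, 2.0, noiseless_config.n_channels)
        ts = simulate_subject(
            noiseless_config, design, "TD", amp, np.random.default_rng(0)
        )
        beta = glm_betas(ts, design)
        np.testing.assert_allclose(beta.values, 1.5 * amp, rtol=1e-6)

    def test_orthogonal_signal_gives_zero_beta(self):
        design = compact_design()
        reg = design.regressor
        q, _ = np.linalg.qr(
            np.column_stack([reg - reg.mean(), np.random.default_rng(0).standard_normal(reg.size)])
        )
        orth = q[:, 1]  # orthogonal to the centered regressor
        beta = glm_betas(orth[None, :], design)
        assert abs(beta.values[0]) < 1e-8

    def test_regressor_itself_gives_unit_beta(self):
        design = compact_design()
        beta = glm_betas(design.regressor[None, :], design)
        assert beta.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_constant_regressor_and_nan_rejected(self):
        design = compact_design()
        with pytest.raises(ValueError):
            glm_betas(np.ones((1, design.n_samples)), design, regressor=np.ones(design.n_samples))
        bad = np.full((1, design.n_samples), np.nan)
        with pytest.raises(ValueError):
            glm_betas(bad, design)


class TestPreprocessCohort:
    def test_noiseless_cohort_full_chain_identity(self, noiseless_config):
        """Detrend + global filter + Hbdiff + GLM recover exactly
        (1 - ratio) * amplitude on noiseless data."""
        cohort = simulate_cohort(noiseless_config, compact_design())
        beta = preprocess_cohort(cohort, PreprocessOptions(cutoff_period=30.0))
        expected = 1.5 * cohort.truth["amplitude_maps"]
        np.testing.assert_allclose(beta.values, expected, rtol=1e-6, atol=1e-9)

    def test_stage_ablation_unbiased_on_noiseless_data(self, noiseless_config):
        cohort = simulate_cohort(noiseless_config, compact_design())
        full = preprocess_cohort(cohort, PreprocessOptions(cutoff_period=30.0))
        glm_only = preprocess_cohort(
            cohort, PreprocessOptions(detrend=False, remove_global=False)
        )
        scale = np.abs(glm_only.values).max()
        assert np.abs(full.values - glm_only.values).max() < 0.05 * scale

    def test_row_order_follows_cohort_order(self, compact_cohort):
        beta = preprocess_cohort(compact_cohort, PreprocessOptions(cutoff_period=30.0))
        reordered = Cohort(
            records=list(reversed(compact_cohort.records)),
            design=compact_cohort.design,
        )
        beta_rev = preprocess_cohort(reordered, PreprocessOptions(cutoff_period=30.0))
        np.testing.assert_allclose(beta.values, beta_rev.values[::-1], atol=1e-12)

    def test_empty_cohort_rejected(self, compact_cohort):
        with pytest.raises(ValueError):
            preprocess_cohort(Cohort(records=[], design=compact_cohort.design))

    def test_high_snr_betas_unbiased(self):
        """Mean recovered beta over many noisy subjects within 5% of the
        injected amplitude when noise is 10% of it."""
        from nirscv import simulate_subject

        cfg = compact_config(
            n_channels=4, noise_sd=0.1, global_sd=0.1, drift_sd=0.05
        )
        design = compact_design()
        amp = np.array([1.0, -1.0, 2.0, 0.5])
        rng = np.random.default_rng(42)
        from nirscv.simulate import SubjectRecord

        records = [
            SubjectRecord(
                f"s{i}", "TD", None,
                simulate_subject(cfg, design, "TD", amp, rng, f"s{i}"),
            )
            for i in range(100)
        ]
        beta = preprocess_cohort(
            Cohort(records=records, design=design),
            PreprocessOptions(cutoff_period=30.0),
        )
        np.testing.assert_allclose(beta.values.mean(axis=0), 1.5 * amp, rtol=0.05)
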