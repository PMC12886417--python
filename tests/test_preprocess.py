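"""Filtering, VASO correction, GLM, PSC, and retinotopy phase analysis."""

import numpy as np
import pytest

from odcdecode import synthetic as syn
from odcdecode.design import RunDesign
from odcdecode.preprocess import (PhaseMapResult, TimeSeries,
                                  dct_highpass_basis, design_matrix, glm_fit,
                                  highpass_filter, percent_signal_change,
                                  percent_signal_change_beta,
                                  retinotopy_phase_map, vaso_bold_correct)

CUTOFF = 1.0 / 270.0


def cosine_series(period_s, n=90, tr=3.0):
    t = tr * np.arange(n)
    return TimeSeries(np.cos(2 * np.pi * t / period_s), tr)


class TestHighpass:
    def test_constant_series_becomes_zero(self):
        out = highpass_filter(TimeSeries(np.full((90, 3), 7.0), 3.0), CUTOFF)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_slow_drift_removed(self):
        # half a 540 s cosine cycle inside a 270 s run
        out = highpass_filter(cosine_series(540.0), CUTOFF)
        assert np.abs(out.data).max() < 0.10

    def test_block_fundamental_preserved(self):
        out = highpass_filter(cosine_series(60.0), CUTOFF)
        assert np.abs(out.data).max() > 0.95

    def test_projection_idempotent(self):
        rng = np.random.default_rng(0)
        ts = TimeSeries(rng.standard_normal((90, 5)), 3.0)
        once = highpass_filter(ts, CUTOFF)
        twice = highpass_filter(once, CUTOFF)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_filter(TimeSeries(np.zeros((90, 1)), 3.0), 1.0 / 6.0)

    def test_filtering_equals_confound_regression(self, reference_design):
        """GLM on the filtered series == unfiltered GLM with the DCT basis
        as confound regressors (orthogonal projection equivalence)."""
        rng = np.random.default_rng(1)
        ts = TimeSeries(rng.standard_normal((90, 4)), 3.0)
        filtered = highpass_filter(ts, CUTOFF)
        basis = dct_highpass_basis(90, 3.0, CUTOFF)
        a = glm_fit(filtered, reference_design)
        b = glm_fit(ts, reference_design, extra_regressors=basis)
        np.testing.assert_allclose(a.contrast, b.contrast, atol=1e-8)


class TestVasoCorrect:
    def test_identical_series_gives_ones(self):
        rng = np.random.default_rng(2)
        data = 100 + rng.standard_normal((54, 4))
        t = 5.0 * np.arange(54)
        a = TimeSeries(data, 5.0, times=t)
        res = vaso_bold_correct(a, TimeSeries(data.copy(), 5.0, times=t),
                                target_tr_s=5.0)
        np.testing.assert_allclose(res.series.data, 1.0)

    def test_constant_ratio_recovered(self):
        rng = np.random.default_rng(3)
        den = 100 + rng.standard_normal((54, 3))
        t = 5.0 * np.arange(54)
        res = vaso_bold_correct(TimeSeries(0.98 * den, 5.0, times=t),
                                TimeSeries(den, 5.0, times=t),
                                target_tr_s=5.0)
        np.testing.assert_allclose(res.series.data, 0.98, rtol=1e-12)

    def test_commutes_with_voxel_permutation(self):
        rng = np.random.default_rng(4)
        t = 5.0 * np.arange(30)
        num = 100 + rng.standard_normal((30, 6))
        den = 100 + rng.standard_normal((30, 6))
        perm = rng.permutation(6)
        direct = vaso_bold_correct(TimeSeries(num, 5, times=t),
                                   TimeSeries(den, 5, times=t), 5.0)
        permuted = vaso_bold_correct(TimeSeries(num[:, perm], 5, times=t),
                                     TimeSeries(den[:, perm], 5, times=t), 5.0)
        np.testing.assert_allclose(permuted.series.data,
                                   direct.series.data[:, perm])

    def test_zero_denominator_voxel_flagged(self):
        t = 5.0 * np.arange(10)
        num = np.ones((10, 2))
        den = np.ones((10, 2))
        den[:, 1] = 0.0
        res = vaso_bold_correct(TimeSeries(num, 5, times=t),
                                TimeSeries(den, 5, times=t), 5.0)
        assert res.undefined[1] and not res.undefined[0]
        np.testing.assert_allclose(res.series.data[:, 1], 1.0)

    def test_correction_reduces_bold_correlation(self, small_sheet,
                                                 small_pattern):
        """Synthetic VASO with small contamination (eps = 0.05) and no CBV
        response: division removes the BOLD component, so the corrected
        series' correlation with the BOLD regressor drops."""
        model = syn.LaminarResponseModel(contrast_type=syn.VASO,
                                         base_amplitude=0.0, noise_sd=0.0)
        design = RunDesign(vaso_pairing=True, n_runs=1)
        sess = syn.simulate_session(small_sheet, small_pattern, model, design,
                                    drift_amplitude=0.0,
                                    bold_contamination_eps=0.05, seed=17)
        run = sess.runs[0]
        d = 5
        ts_n = TimeSeries(run.nulled[d], 5.0, times=run.nulled_times)
        ts_nn = TimeSeries(run.not_nulled[d], 5.0, times=run.not_nulled_times)
        corrected = vaso_bold_correct(ts_n, ts_nn).series
        x, _ = design_matrix(run.design)
        bold_reg = x[:, 0] + x[:, 1]
        strong = np.abs(small_pattern.ocularity) > 0.5

        def mean_corr(ts):
            reg = np.interp(ts.times, 3.0 * np.arange(90), bold_reg)
            data = ts.data[:, strong]
            return np.mean([np.corrcoef(reg, data[:, v])[0, 1]
                            for v in range(data.shape[1])])

        assert mean_corr(corrected) < mean_corr(ts_n) - 0.5


class TestGlm:
    def test_null_z_scores_calibrated(self, reference_design):
        rng = np.random.default_rng(5)
        ts = TimeSeries(rng.standard_normal((90, 1000)), 3.0)
        res = glm_fit(ts, reference_design)
        frac = np.mean(np.abs(res.z) > 1.96)
        assert 0.03 <= frac <= 0.07

    def test_all_zero_series_flagged(self, reference_design):
        res = glm_fit(TimeSeries(np.zeros((90, 3)), 3.0), reference_design)
        np.testing.assert_allclose(res.betas, 0.0)
        assert res.undefined.all()
        assert np.isnan(res.z).all()

    def test_rank_deficient_design_names_columns(self, reference_design):
        dup = np.ones((90, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="collinear.*confound0"):
            glm_fit(TimeSeries(np.random.default_rng(0)
                               .standard_normal((90, 2)), 3.0),
                    reference_design, extra_regressors=dup)

    def test_concatenated_runs_fit(self, reference_design):
        designs = [reference_design, reference_design.with_conditions(
            ("right", "left") * 4)]
        rng = np.random.default_rng(6)
        ts = TimeSeries(rng.standard_normal((180, 5)), 3.0)
        res = glm_fit(ts, designs)
        assert res.betas.shape[0] == 4  # left, right, 2 intercepts
        assert res.dof == 180 - 4


class TestPsc:
    def test_definition(self, reference_design):
        data = np.full((90, 1), 100.0)
        data[reference_design.retained_mask()] = 102.0
        res = percent_signal_change(TimeSeries(data, 3.0), reference_design)
        np.testing.assert_allclose(res.psc, 2.0)

    def test_null_case(self, reference_design):
        res = percent_signal_change(TimeSeries(np.full((90, 2), 50.0), 3.0),
                                    reference_design)
        np.testing.assert_allclose(res.psc, 0.0)

    def test_zero_baseline_flagged(self, reference_design):
        data = np.zeros((90, 1))
        data[reference_design.retained_mask()] = 1.0
        res = percent_signal_change(TimeSeries(data, 3.0), reference_design)
        assert res.undefined[0] and np.isnan(res.psc[0])

    def test_drained_psc_increases_toward_pial(self, small_sheet,
                                               small_pattern):
        """Noise-free GE-BOLD with drain: PSC strictly increases from GM/WM
        to GM/CSF (running-sum construction)."""
        model = syn.LaminarResponseModel(drain_lambda=2.0, noise_sd=0.0)
        design = RunDesign(n_runs=1)
        sess = syn.simulate_session(small_sheet, small_pattern, model, design,
                                    drift_amplitude=0.0, seed=19)
        run = sess.runs[0]
        strong = np.abs(small_pattern.ocularity) > 0.5
        psc = [percent_signal_change(TimeSeries(run.series[d], 3.0),
                                     run.design).psc[strong].mean()
               for d in range(model.n_depths)]
        assert np.all(np.diff(psc) > 0)

    def test_beta_estimator_close_to_block_mean(self, noisefree_session):
        run = noisefree_session.runs[0]
        ts = TimeSeries(run.series[5], 3.0)
        a = percent_signal_change(ts, run.design).psc
        b = percent_signal_change_beta(ts, run.design).psc
        # same quantity up to transient/HRF edge effects
        assert np.corrcoef(a, b)[0, 1] > 0.99


class TestRetinotopy:
    def make_run(self, phase, n=276, tr=2.0, period=64.0, amp=1.0, noise=0.0,
                 seed=0):
        t = tr * np.arange(n)
        rng = np.random.default_rng(seed)
        data = amp * np.cos(2 * np.pi * t / period - phase)[:, None]
        data = data + noise * rng.standard_normal((n, 1))
        return TimeSeries(data, tr)

    def test_opposite_direction_averaging_cancels_lag(self):
        phi0, lag = 1.1, 0.4
        fwd = self.make_run(phi0 + lag)
        rev = self.make_run(-phi0 + lag)
        res = retinotopy_phase_map(fwd, rev, cycles=8.25, cycle_period_s=64.0)
        assert res.phase[0] == pytest.approx(phi0, abs=1e-6)

    def test_amplitude_of_pure_sinusoid(self):
        fwd = self.make_run(0.3, amp=2.0)
        rev = self.make_run(-0.3, amp=2.0)
        res = retinotopy_phase_map(fwd, rev, 8.25, 64.0)
        assert res.amplitude[0] == pytest.approx(2.0, rel=1e-3)

    def test_noise_voxel_amplitude_near_floor_phase_uniform(self):
        phases = []
        for seed in range(40):
            fwd = self.make_run(0, amp=0.0, noise=1.0, seed=2 * seed)
            rev = self.make_run(0, amp=0.0, noise=1.0, seed=2 * seed + 1)
            res = retinotopy_phase_map(fwd, rev, 8.25, 64.0)
            assert res.amplitude[0] < 0.5
            phases.append(res.phase[0])
        phases = np.array(phases)
        # uniform phase: resultant vector length small
        resultant = np.abs(np.mean(np.exp(1j * phases)))
        assert resultant < 0.4

    def test_zero_series_flagged(self):
        z = TimeSeries(np.zeros((276, 1)), 2.0)
        res = retinotopy_phase_map(z, z, 8.25, 64.0)
        assert res.amplitude[0] == 0.0
        assert np.isnan(res.phase[0])

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            retinotopy_phase_map(TimeSeries(np.zeros((10, 1)), 2.0),
                                 TimeSeries(np.zeros((12, 1)), 2.0), 8.25, 64.0)
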