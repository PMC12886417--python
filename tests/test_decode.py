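"""Time-point retention, feature selection, and LORO SVM decoding."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.feature_selection import f_classif

from conftest import vertex_samples
from odcdecode import synthetic as syn
from odcdecode.decode import (DEPTH_AVERAGED, PER_DEPTH, DecoderConfig,
                              LabeledSamples, anova_f_scores,
                              feature_count_sweep, loro_cross_validate,
                              select_features, select_timepoints,
                              session_samples, single_depth)
from odcdecode.design import RunDesign


class TestRetention:
    def test_reference_design_counts(self, reference_design):
        """90 volumes, 8 blocks of 10, two 5-volume baselines -> 64 retained,
        32 per eye; 9 training runs -> 576 time points."""
        series = np.zeros((2, 90, 10))
        s = select_timepoints(series, reference_design)
        assert s.n_samples == 64
        assert (s.labels == "left").sum() == 32
        assert (s.labels == "right").sum() == 32
        assert 9 * s.n_samples == 576

    def test_short_block_arithmetic(self):
        # two 5-volume blocks, no baseline: (5 - 2) * 2 = 6 retained
        design = RunDesign(tr_s=1.0, n_volumes=10, baseline_s=0.0,
                           block_s=5.0, block_conditions=("left", "right"))
        s = select_timepoints(np.zeros((1, 10, 4)), design)
        assert s.n_samples == 6
        assert (s.labels == "left").sum() == 3

    def test_block_shorter_than_three_volumes_rejected(self):
        design = RunDesign(tr_s=1.0, n_volumes=4, baseline_s=0.0,
                           block_s=2.0, block_conditions=("left", "right"))
        with pytest.raises(ValueError, match="retain"):
            select_timepoints(np.zeros((1, 4, 2)), design)

    def test_unbalanced_run_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            LabeledSamples(np.zeros((1, 4, 2)),
                           np.array(["left"] * 3 + ["right"]),
                           np.zeros(4, int))


class TestAnovaF:
    def test_identical_class_means_give_zero(self):
        x = np.array([[1.0], [2.0], [1.0], [2.0]])
        s = LabeledSamples(x[None], np.array(["left", "left", "right",
                                              "right"]), np.zeros(4, int))
        assert anova_f_scores(s)[0] == 0.0

    def test_hand_computed_example(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5 (df 1), MSW = 1 -> F = 13.5
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        s = LabeledSamples(x[None], np.array(["left"] * 3 + ["right"] * 3),
                           np.zeros(6, int))
        assert anova_f_scores(s)[0] == pytest.approx(13.5)

    def test_equals_squared_t_statistic(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((20, 30))
        labels = np.array(["left"] * 10 + ["right"] * 10)
        s = LabeledSamples(x[None], labels, np.zeros(20, int))
        f = anova_f_scores(s)
        t, _ = sps.ttest_ind(x[:10], x[10:], equal_var=True)
        np.testing.assert_allclose(f, t**2, atol=1e-10)

    def test_matches_sklearn_f_classif(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 25))
        labels = np.array(["left", "right"] * 20)
        s = LabeledSamples(x[None], labels, np.repeat(np.arange(2), 20))
        f_ours = anova_f_scores(s)
        f_ref, _ = f_classif(x, labels)
        np.testing.assert_allclose(f_ours, f_ref, rtol=1e-10)

    def test_tiny_class_rejected(self):
        s = LabeledSamples(np.zeros((1, 2, 3)), np.array(["left", "right"]),
                           np.zeros(2, int))
        with pytest.raises(ValueError, match="2 samples"):
            anova_f_scores(s)


class TestSelectFeatures:
    def make_samples(self, n_depths=3, n_vertices=20, informative=4,
                     seed=9, per_depth_shift=False):
        rng = np.random.default_rng(seed)
        labels = np.array(["left", "right"] * 32)
        runs = np.repeat(np.arange(4), 16)
        x = rng.standard_normal((n_depths, 64, n_vertices))
        signal = np.where(labels == "left", 1.0, -1.0)
        for d in range(n_depths):
            v = informative + d if per_depth_shift else informative
            x[d, :, v] += 3.0 * signal
        return LabeledSamples(x, labels, runs)

    def test_single_informative_vertex_found(self):
        s = self.make_samples()
        sel = select_features(s, DEPTH_AVERAGED, k=1)
        assert list(sel.selected) == [4]

    def test_depth_averaged_identical_across_depths(self):
        s = self.make_samples()
        sel = select_features(s, DEPTH_AVERAGED, k=5)
        for d in range(s.n_depths):
            np.testing.assert_array_equal(sel.selected_at(d), sel.selected)

    def test_per_depth_policy_tracks_depth_specific_signal(self):
        s = self.make_samples(per_depth_shift=True)
        sel = select_features(s, PER_DEPTH, k=1)
        assert [sel.selected_at(d)[0] for d in range(3)] == [4, 5, 6]

    def test_single_depth_policy_reuses_one_depth(self):
        s = self.make_samples(per_depth_shift=True)
        sel = select_features(s, single_depth(2), k=1)
        for d in range(3):
            assert sel.selected_at(d)[0] == 6

    def test_ties_broken_by_ascending_index(self):
        x = np.zeros((1, 8, 5))
        labels = np.array(["left", "right"] * 4)
        x[0, :, 2] = np.where(labels == "left", 1, -1)
        x[0, :, 4] = x[0, :, 2]  # identical score
        s = LabeledSamples(x, labels, np.repeat([0, 1], 4))
        sel = select_features(s, DEPTH_AVERAGED, k=1)
        assert sel.selected[0] == 2

    def test_k_above_eligible_warns_and_selects_all(self):
        s = self.make_samples(n_vertices=6)
        with pytest.warns(UserWarning, match="eligible"):
            sel = select_features(s, DEPTH_AVERAGED, k=50)
        assert len(sel.selected) == 6

    def test_eligibility_mask_respected(self):
        s = self.make_samples()
        mask = np.ones(20, bool)
        mask[4] = False  # exclude the informative vertex
        sel = select_features(s, DEPTH_AVERAGED, k=3, eligible=mask)
        assert 4 not in sel.selected

    def test_drain_changes_depth_specific_selections(self, small_sheet,
                                                     small_pattern):
        """With pial-ward draining, the vertices scored best at the GM/WM
        surface differ from those at the GM/CSF surface."""
        model = syn.LaminarResponseModel(drain_lambda=3.0, noise_sd=5.0)
        sess = syn.simulate_session(small_sheet, small_pattern, model,
                                    RunDesign(n_runs=4), seed=23)
        samples = vertex_samples(sess)
        deep = select_features(samples, single_depth(0), k=50)
        pial = select_features(samples, single_depth(10), k=50)
        assert set(deep.selected) != set(pial.selected)


class TestLoroDecoding:
    def test_separable_samples_decode_perfectly(self):
        """Constructed separability: disjoint class means far beyond the
        noise give accuracy exactly 1.0 at every depth and fold."""
        rng = np.random.default_rng(31)
        labels = np.tile(np.array(["left", "right"] * 8), 4)
        runs = np.repeat(np.arange(4), 16)
        x = 0.01 * rng.standard_normal((3, 64, 20))
        x[:, :, :10] += np.where(labels == "left", 5.0, -5.0)[None, :, None]
        s = LabeledSamples(x, labels, runs)
        res = loro_cross_validate(s, DecoderConfig(k_features=10))
        np.testing.assert_allclose(res.accuracies, 1.0)

    def test_noise_free_session_decodes_near_perfectly(self, noisefree_session):
        """A noise-free simulated session decodes essentially perfectly;
        only block-transition volumes where the rising and decaying
        hemodynamic responses cross can remain ambiguous."""
        samples = vertex_samples(noisefree_session)
        res = loro_cross_validate(samples, DecoderConfig(k_features=100))
        assert res.accuracies.mean() > 0.99
        assert np.median(res.accuracies) == 1.0

    def test_single_run_rejected(self, noisefree_session):
        samples = vertex_samples(noisefree_session)
        one_run = samples.subset(samples.run_ids == 0)
        with pytest.raises(ValueError, match="2 runs"):
            loro_cross_validate(one_run)

    def test_no_leakage_from_held_out_run(self, noisy_session):
        """Corrupting the held-out run must not change the features selected
        or the standardization of its training folds."""
        samples = vertex_samples(noisy_session)
        corrupted = LabeledSamples(samples.data.copy(), samples.labels,
                                   samples.run_ids)
        rng = np.random.default_rng(0)
        corrupted.data[:, samples.run_ids == 0] = \
            1e3 * rng.standard_normal(corrupted.data[:, samples.run_ids == 0].shape)
        cfg = DecoderConfig(k_features=50)
        train_mask = samples.run_ids != 0
        sel_a = select_features(samples.subset(train_mask),
                                cfg.selection_policy, cfg.k_features)
        sel_b = select_features(corrupted.subset(train_mask),
                                cfg.selection_policy, cfg.k_features)
        np.testing.assert_array_equal(sel_a.selected, sel_b.selected)
        np.testing.assert_array_equal(sel_a.scores, sel_b.scores)
        # standardization parameters come from the training folds only
        cols = sel_a.selected
        np.testing.assert_allclose(
            samples.subset(train_mask).data[0][:, cols].mean(axis=0),
            corrupted.subset(train_mask).data[0][:, cols].mean(axis=0))

    def test_constant_feature_warns(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((1, 32, 5))
        x[:, :, 0] = 7.0  # constant vertex
        labels = np.array(["left", "right"] * 16)
        s = LabeledSamples(x, labels, np.repeat(np.arange(2), 16))
        with pytest.warns(UserWarning, match="constant"):
            loro_cross_validate(s, DecoderConfig(k_features=5))

    def test_class_balance_preserved_through_retention(self, noisy_session):
        samples = vertex_samples(noisy_session)
        for r in np.unique(samples.run_ids):
            sel = samples.run_ids == r
            assert (samples.labels[sel] == "left").sum() == 32
            assert (samples.labels[sel] == "right").sum() == 32


@pytest.fixture(scope="module")
def small_samples():
    rng = np.random.default_rng(12)
    labels = np.tile(np.array(["left", "right"] * 8), 4)
    runs = np.repeat(np.arange(4), 16)
    x = rng.standard_normal((2, 64, 30))
    signal = np.where(labels == "left", 1.0, -1.0)
    x[:, :, :10] += 1.0 * signal[None, :, None]
    return LabeledSamples(x, labels, runs)


class TestFeatureCountSweep:
    def test_boundary_k_equals_all_vertices(self, small_samples):
        cfg = DecoderConfig(k_features=5)
        acc, _ = feature_count_sweep(small_samples, cfg, [30])
        assert acc.shape == (1, 2)
        assert np.all(acc > 0.5)

    def test_k_of_one_matches_single_feature_decoder(self, small_samples):
        cfg = DecoderConfig(k_features=1)
        direct = loro_cross_validate(small_samples, cfg).mean_by_depth
        swept, _ = feature_count_sweep(small_samples, cfg, [1])
        np.testing.assert_allclose(swept[0], direct)

    def test_accuracy_grows_with_k_on_clean_signal(self, noisefree_session):
        samples = vertex_samples(noisefree_session)
        cfg = DecoderConfig()
        acc, _ = feature_count_sweep(samples, cfg, [1, 20])
        assert np.all(acc[1] >= acc[0] - 1e-12)

    def test_psc_surface_uses_selected_vertices(self, small_samples):
        psc_maps = np.arange(60, dtype=float).reshape(2, 30)
        cfg = DecoderConfig(k_features=5)
        acc, psc = feature_count_sweep(small_samples, cfg, [2, 30],
                                       psc_maps=psc_maps)
        assert psc.shape == acc.shape
        # with all vertices selected the PSC is the plain mean
        np.testing.assert_allclose(psc[1], psc_maps.mean(axis=1))

    def test_empty_grid_rejected(self, small_samples):
        with pytest.raises(ValueError, match="nonempty"):
            feature_count_sweep(small_samples, DecoderConfig(), [])
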