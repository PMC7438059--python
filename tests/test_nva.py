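"""Neural vector angle: identities, invariances, clustering, mode tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gripstate.behavior import detect_onsets, kinematic_pc1
from gripstate.nva import (
    compare_modes_nva,
    neural_vector_angle,
    nva_time_course,
    select_feature_clusters,
    trial_averaged_traces,
)


class TestAngle:
    def test_identical_vectors_give_zero_degrees(self):
        v = np.array([1.0, 2.0, 3.0])
        assert neural_vector_angle(v, v) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_vectors_give_ninety_degrees(self):
        assert neural_vector_angle(
            np.array([1.0, 0.0]), np.array([0.0, 2.0])
        ) == pytest.approx(90.0)

    def test_antiparallel_vectors_give_180_degrees(self):
        v = np.array([1.0, -2.0])
        assert neural_vector_angle(-v, v) == pytest.approx(180.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((20, 6))
        ref = rng.standard_normal(6)
        a = neural_vector_angle(m, ref)
        b = neural_vector_angle(17.3 * m, 0.004 * ref)
        assert np.allclose(a, b)

    def test_angles_stay_in_range(self):
        rng = np.random.default_rng(1)
        th = neural_vector_angle(rng.standard_normal((500, 8)), rng.standard_normal(8))
        assert np.nanmin(th) >= 0.0 and np.nanmax(th) <= 180.0

    def test_near_zero_norm_is_reported_missing(self):
        th = neural_vector_angle(np.zeros((3, 4)), np.ones(4))
        assert np.all(np.isnan(th))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            neural_vector_angle(np.ones(3), np.ones(4))


class TestClusterSelection:
    def _three_group_traces(self, n_per=6, bins=40):
        t = np.linspace(0, 1, bins)
        flat = np.zeros(bins)
        up = np.sin(np.pi * t)
        down = -np.sin(np.pi * t)
        traces, bands = [], []
        for g, proto in enumerate((flat, up, down)):
            for i in range(n_per):
                traces.append(proto)
                bands.append("high" if g == 1 else "low")
        return np.array(traces), bands

    def test_separable_groups_are_partitioned_perfectly(self):
        traces, bands = self._three_group_traces()
        fc = select_feature_clusters(traces, bands, k=3, seed=0)
        labels = fc.labels
        # identical traces share a cluster; distinct prototypes do not
        for g in range(3):
            grp = labels[g * 6 : (g + 1) * 6]
            assert len(set(grp)) == 1
        assert len({labels[0], labels[6], labels[12]}) == 3
        assert np.all(fc.silhouette > 0.9)

    def test_k_three_maximizes_mean_silhouette(self):
        traces, bands = self._three_group_traces()
        rng = np.random.default_rng(0)
        noisy = traces + 0.02 * rng.standard_normal(traces.shape)
        scores = {}
        for k in range(2, 6):
            fc = select_feature_clusters(noisy, bands, k=k, seed=0)
            scores[k] = fc.silhouette.mean()
        assert max(scores, key=scores.get) == 3

    def test_selected_clusters_are_the_modulated_ones_tagged_by_band(self):
        traces, bands = self._three_group_traces()
        fc = select_feature_clusters(traces, bands, k=3, seed=0)
        assert set(fc.selected) == {"low", "high"}
        assert fc.selected["low"] != fc.selected["high"]
        flat_cluster = fc.labels[0]
        assert flat_cluster not in fc.selected.values()

    def test_simulator_session_selects_one_cluster_per_band(
        self, small_features, detected_trials
    ):
        avg, _ = trial_averaged_traces(small_features, detected_trials)
        bands = [b for _, b in small_features.feature_index]
        fc = select_feature_clusters(avg, bands, k=3, seed=1)
        low_members = [bands[i] for i in fc.features_in("low")]
        high_members = [bands[i] for i in fc.features_in("high")]
        assert np.mean(np.array(low_members) == "low") > 0.5
        assert np.mean(np.array(high_members) == "high") > 0.5


class TestTimeCourse:
    def test_smoothing_span_is_125_ms(self, small_features):
        assert 5 * small_features.step_s == pytest.approx(0.125)

    def test_reference_window_self_similarity(self):
        """Constant-amplitude features -> theta within the reference window
        stays below one degree."""
        from gripstate.features import FeatureTensor
        from gripstate.nva import FeatureClustering

        n_bins = 200
        vals = np.tile(np.array([1.0, 2.0, 0.5, 1.5]), (n_bins, 1))
        ft = FeatureTensor(vals, np.arange(n_bins) * 0.025, 0.256, 0.025,
                           [(0, "low"), (0, "high"), (1, "low"), (1, "high")])
        fc = FeatureClustering(
            labels=np.array([0, 1, 0, 1]), k=2,
            silhouette=np.ones(4), selected={"low": 0, "high": 1},
        )
        trials = pd.DataFrame(
            {
                "cue_time_s": [1.0], "movement_onset_s": [1.8],
                "force_onset_s": [2.2], "peak_force_time_s": [3.0],
                "force_end_s": [3.2], "force_target": [0.5],
                "outcome": ["matched"], "valid": [True],
            }
        )
        res = nva_time_course(ft, fc, trials)
        for th in res.theta.values():
            assert np.nanmax(th) < 1.0

    def test_high_band_angle_drops_toward_force_peak(
        self, small_features, detected_trials
    ):
        """With planted modulation the high-band NVA is far from the
        reference early in the trial and approaches 0 near peak force."""
        avg, _ = trial_averaged_traces(small_features, detected_trials)
        bands = [b for _, b in small_features.feature_index]
        fc = select_feature_clusters(avg, bands, k=3, seed=1)
        res = nva_time_course(small_features, fc, detected_trials)
        th = np.nanmean(res.theta["high"], axis=0)
        early = th[res.rel_times < -1.0].mean()
        late = th[(res.rel_times > 0.2) & (res.rel_times < 0.6)].mean()
        assert late < early


class TestModeComparison:
    def test_identical_mode_distributions_rarely_reject(self):
        """Angles drawn from one distribution for every mode -> the
        Kruskal-Wallis test keeps its nominal size."""
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [rng.uniform(0, 180, 120) for _ in range(3)]
            _, p = stats.kruskal(*samples)
            rejections += p < 0.05
        assert rejections <= 2

    def test_planted_modulation_separates_modes(self, small_features, detected_trials):
        avg, _ = trial_averaged_traces(small_features, detected_trials)
        bands = [b for _, b in small_features.feature_index]
        fc = select_feature_clusters(avg, bands, k=3, seed=1)
        res = nva_time_course(small_features, fc, detected_trials)
        out = compare_modes_nva(res, detected_trials)
        assert out["high"]["p"] < 0.05
        assert set(out["high"]["modes"]) == {"premovement", "movement", "force"}

    def test_two_mode_degenerate_input_runs_with_flag(self, small_features, detected_trials):
        avg, _ = trial_averaged_traces(small_features, detected_trials)
        bands = [b for _, b in small_features.feature_index]
        fc = select_feature_clusters(avg, bands, k=3, seed=1)
        # restrict the window so the force mode never appears
        res = nva_time_course(small_features, fc, detected_trials,
                              pre_s=1.2, post_s=-0.3)
        out = compare_modes_nva(res, detected_trials)
        assert out["high"]["flags"]
        assert "force" not in out["high"]["modes"]

    def test_permuting_features_within_cluster_leaves_theta_unchanged(
        self, small_features, detected_trials
    ):
        from gripstate.features import FeatureTensor

        avg, _ = trial_averaged_traces(small_features, detected_trials)
        bands = [b for _, b in small_features.feature_index]
        fc = select_feature_clusters(avg, bands, k=3, seed=1)
        res1 = nva_time_course(small_features, fc, detected_trials)
        # permute the columns of one selected cluster (and the labels with
        # them): the angle is a symmetric function of cluster members
        cols = fc.features_in("high")
        perm = np.roll(cols, 1)
        vals = small_features.values.copy()
        vals[:, cols] = vals[:, perm]
        labels = fc.labels.copy()
        ft2 = FeatureTensor(vals, small_features.bin_times, small_features.window_s,
                            small_features.step_s, small_features.feature_index)
        fc2 = type(fc)(labels=labels, k=fc.k, silhouette=fc.silhouette,
                       selected=fc.selected)
        res2 = nva_time_course(ft2, fc2, detected_trials)
        assert np.allclose(res1.theta["high"], res2.theta["high"], equal_nan=True)
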