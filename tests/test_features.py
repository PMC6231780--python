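"""Feature layer: preprocessing, segmentation, clustering, entropy, circadian
power and the weekly feature vector invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenogroup as pg
from phenogroup.features import (
    FeatureConfig,
    HomeUndeterminableError,
    StationarySegment,
    cluster_locations,
    compute_diurnal_power,
    compute_entropy,
    extract_features,
    identify_home,
    preprocess_trace,
    segment_stationary,
)
from phenogroup.utils import FEATURE_NAMES, haversine_km


def _trace(rows):
    return pd.DataFrame(rows, columns=["timestamp", "latitude", "longitude", "accuracy_m"])


def _ts(s):
    return pd.Timestamp(s, tz="UTC")


class TestPreprocess:
    def test_empty_input_gives_empty_output(self):
        assert preprocess_trace(_trace([])).empty

    def test_duplicate_timestamp_keeps_most_accurate(self):
        t = _ts("2024-01-01 10:00")
        df = _trace([(t, 51.0, 0.0, 200.0), (t, 51.0, 0.0, 10.0)])
        out = preprocess_trace(df, max_accuracy_m=100.0)
        assert len(out) == 1 and out["accuracy_m"].iloc[0] == 10.0

    def test_shuffled_input_is_sorted(self, rng):
        times = [_ts("2024-01-01") + pd.Timedelta(minutes=m) for m in range(20)]
        df = _trace([(t, 51.0, 0.0, 10.0) for t in times]).sample(frac=1, random_state=1)
        out = preprocess_trace(df)
        assert out["timestamp"].is_monotonic_increasing and len(out) == 20

    def test_inaccurate_fixes_dropped(self):
        df = _trace([(_ts("2024-01-01"), 51.0, 0.0, 150.0)])
        assert preprocess_trace(df, max_accuracy_m=100.0).empty


class TestSegmentation:
    def test_constant_position_single_segment_no_transition(self):
        times = [_ts("2024-01-01") + pd.Timedelta(minutes=5 * i) for i in range(24)]
        df = _trace([(t, 51.0, 0.0, 10.0) for t in times])
        segments, transitions = segment_stationary(df)
        assert len(segments) == 1 and not transitions
        assert segments[0].dwell_s == pytest.approx(23 * 300)

    def test_constant_fast_movement_all_transition(self):
        # 60 km/h due north: 1 km per minute ~ 0.009 degrees latitude
        times = [_ts("2024-01-01") + pd.Timedelta(minutes=i) for i in range(30)]
        df = _trace([(t, 50.0 + i / 111.195, 0.0, 10.0) for i, t in enumerate(times)])
        segments, transitions = segment_stationary(df)
        assert not segments
        assert len(transitions) == 1
        span = (transitions[0][1] - transitions[0][0]).total_seconds()
        assert span == pytest.approx(29 * 60)

    def test_unsorted_input_rejected(self):
        df = _trace(
            [(_ts("2024-01-01 01:00"), 51.0, 0.0, 10.0), (_ts("2024-01-01 00:00"), 51.0, 0.0, 10.0)]
        )
        with pytest.raises(ValueError, match="sorted"):
            segment_stationary(df)

    def test_synthetic_transition_fraction_matches_construction(self):
        anchors = [(51.75, -1.25), (51.76, -1.25)]  # ~1.11 km apart, ~13.3 min walk
        tc = pg.TraceConfig(
            anchor_locations=anchors,
            daily_schedule=[((0, 12), 0), ((12, 24), 1)],
            gps_noise_sd_m=0.0,
            sampling_interval_s=60.0,
            n_days=2,
            seed=0,
        )
        trace = pg.generate_geolocation_trace(tc)
        segments, transitions = segment_stationary(trace)
        walk_s = haversine_km(51.75, -1.25, 51.76, -1.25) / 5.0 * 3600.0
        measured = sum((b - a).total_seconds() for a, b in transitions)
        n_transitions = 3  # two boundary walks day 1->2 plus one midday walk each day
        assert measured == pytest.approx(n_transitions * walk_s, abs=n_transitions * 60.0)


def _seg(start_min, dur_min, lat, lon):
    t0 = _ts("2024-01-01") + pd.Timedelta(minutes=start_min)
    return StationarySegment(t0, t0 + pd.Timedelta(minutes=dur_min), (lat, lon))


class TestClustering:
    def test_single_segment_gets_cluster_zero(self):
        seg = _seg(0, 60, 51.0, 0.0)
        centroids = cluster_locations([seg])
        assert seg.cluster_id == 0 and 0 in centroids

    def test_nearby_centroids_merge(self):
        a, b = _seg(0, 60, 51.0, 0.0), _seg(120, 30, 51.00045, 0.0)  # ~50 m apart
        cluster_locations([a, b], distance_threshold_m=200.0)
        assert a.cluster_id == b.cluster_id == 0

    def test_greedy_chain_merge_through_highest_dwell_leader(self):
        """Three stays at pairwise distances ~150/150/290 m: when the middle
        one has the most dwell it founds the cluster and both others join,
        exactly as the greedy leader rule prescribes when run by hand."""
        m_per_deg = 111_195.0
        mid = _seg(0, 120, 51.0, 0.0)  # leader (largest dwell)
        left = _seg(180, 30, 51.0 - 150.0 / m_per_deg, 0.0)
        right = _seg(240, 30, 51.0 + 140.0 / m_per_deg, 0.0)
        centroids = cluster_locations([mid, left, right], distance_threshold_m=200.0)
        assert len(centroids) == 1
        assert {mid.cluster_id, left.cluster_id, right.cluster_id} == {0}
        # sanity: the far pair is beyond the threshold on its own
        assert haversine_km(left.centroid[0], 0, right.centroid[0], 0) * 1000 > 200

    def test_cluster_ids_ordered_by_dwell(self):
        big = _seg(0, 300, 51.0, 0.0)
        small = _seg(400, 30, 52.0, 0.0)
        cluster_locations([small, big])
        assert big.cluster_id == 0 and small.cluster_id == 1


class TestHome:
    def test_single_cluster_is_home(self):
        seg = _seg(0, 600, 51.0, 0.0)  # spans past 06:00
        cluster_locations([seg])
        assert identify_home([seg]) == 0

    def test_tie_breaks_to_lower_cluster_id(self):
        a = _seg(0, 180, 51.0, 0.0)  # 00:00-03:00
        b = _seg(180, 180 + 60, 52.0, 0.0)  # 03:00-07:00 -> 3h night + extra dwell
        cluster_locations([a, b])
        # both have 3 h of night dwell; b has more total dwell so holds id 0
        assert identify_home([a, b]) == min(a.cluster_id, b.cluster_id)

    def test_no_night_data_raises(self):
        seg = _seg(8 * 60, 60, 51.0, 0.0)  # 08:00-09:00 only
        cluster_locations([seg])
        with pytest.raises(HomeUndeterminableError):
            identify_home([seg])


class TestEntropy:
    def test_single_place_zero_entropy(self):
        assert compute_entropy([1.0]) == (0.0, 0.0)

    def test_uniform_two_places(self):
        ent, nent = compute_entropy([0.5, 0.5])
        assert ent == pytest.approx(np.log(2)) and nent == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        p = [0.7, 0.2, 0.1]
        oracle = -sum(pi * np.log(pi) for pi in p)
        ent, nent = compute_entropy(p)
        assert ent == pytest.approx(oracle)
        assert nent == pytest.approx(oracle / np.log(3))

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            compute_entropy([0.5, 0.4])
        with pytest.raises(ValueError):
            compute_entropy([1.2, -0.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    def test_entropy_bounded_by_log_n(self, weights):
        p = np.array(weights) / np.sum(weights)
        ent, nent = compute_entropy(p)
        assert -1e-9 <= ent <= np.log(p.size) + 1e-9
        assert -1e-9 <= nent <= 1 + 1e-9


class TestDiurnalPower:
    def test_constant_signal_zero_power(self):
        t = np.linspace(0, 168, 200)
        assert compute_diurnal_power(t, np.full_like(t, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_pure_24h_sinusoid_recovers_amplitude_squared(self):
        t = np.linspace(0, 168, 2000)
        A = 2.5
        v = A * np.sin(2 * np.pi * t / 24.0 + 0.7)
        assert compute_diurnal_power(t, v) == pytest.approx(A**2, rel=1e-6)

    def test_12h_sinusoid_weaker_than_24h(self):
        t = np.linspace(0, 168, 2000)
        p24 = compute_diurnal_power(t, np.sin(2 * np.pi * t / 24.0))
        p12 = compute_diurnal_power(t, np.sin(2 * np.pi * t / 12.0))
        assert p12 < p24

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            compute_diurnal_power([0.0, 1.0], [1.0, 2.0])


class TestWeeklyFeatures:
    @staticmethod
    def _home_week(noise=0.0, seed=0):
        tc = pg.TraceConfig(
            anchor_locations=[(51.75, -1.25)],
            daily_schedule=[((0, 24), 0)],
            gps_noise_sd_m=noise,
            sampling_interval_s=600.0,
            n_days=7,
            seed=seed,
        )
        return pg.generate_geolocation_trace(tc)

    def test_degenerate_all_home_week(self):
        feats = extract_features(self._home_week()).iloc[0]
        assert feats["n_clusters"] == 1
        assert feats["home_stay"] == pytest.approx(100.0)
        assert feats["transition_time"] == pytest.approx(0.0)
        assert feats["total_distance"] == pytest.approx(0.0, abs=1e-9)
        assert feats["entropy"] == pytest.approx(0.0)
        for col in ("diurnal_movement", "diurnal_movement_normalized", "diurnal_movement_home_distance"):
            assert feats[col] == pytest.approx(0.0, abs=1e-9)

    def test_meridian_degree_hop_distance(self):
        t0 = _ts("2024-01-01")
        df = _trace([(t0, 50.0, 0.0, 10.0), (t0 + pd.Timedelta(hours=1), 51.0, 0.0, 10.0)])
        from phenogroup.features import compute_weekly_features

        feats = compute_weekly_features(df, [], {}, None, t0.normalize())
        assert feats["total_distance"] == pytest.approx(111.195, abs=0.005)

    def test_home_work_week_matches_schedule(self):
        tc = pg.TraceConfig(
            anchor_locations=[(51.75, -1.25), (51.76, -1.26)],
            daily_schedule=[((0, 9), 0), ((9, 17), 1), ((17, 24), 0)],
            gps_noise_sd_m=3.0,
            sampling_interval_s=300.0,
            n_days=7,
            seed=4,
        )
        feats = extract_features(pg.generate_geolocation_trace(tc)).iloc[0]
        assert feats["n_clusters"] == 2
        assert feats["home_stay"] == pytest.approx(100.0 * 16 / 24, abs=2.0)

    def test_total_distance_invariant_under_time_reversal(self):
        trace = self._home_week(noise=20.0, seed=7)
        fwd = extract_features(trace).iloc[0]["total_distance"]
        rev = trace.iloc[::-1].reset_index(drop=True).copy()
        rev["latitude"] = trace["latitude"].to_numpy()[::-1]
        rev["longitude"] = trace["longitude"].to_numpy()[::-1]
        rev["timestamp"] = trace["timestamp"].to_numpy()  # restore increasing time
        back = extract_features(rev).iloc[0]["total_distance"]
        assert back == pytest.approx(fwd, rel=1e-9)

    def test_feature_vector_invariants_on_noisy_week(self):
        tc = pg.TraceConfig(
            anchor_locations=[(51.75, -1.25), (51.76, -1.26), (51.74, -1.27)],
            daily_schedule=[((0, 8), 0), ((8, 13), 1), ((13, 18), 2), ((18, 24), 0)],
            gps_noise_sd_m=15.0,
            sampling_interval_s=300.0,
            n_days=14,
            seed=5,
        )
        feats = extract_features(pg.generate_geolocation_trace(tc))
        assert len(feats) == 2
        for _, f in feats.iterrows():
            assert 0 <= f["home_stay"] <= 100
            assert 0 <= f["transition_time"] <= 100
            assert f["home_stay"] + f["transition_time"] <= 100 + 1e-9
            assert f["n_clusters"] >= 1
            assert 0 <= f["normalized_entropy"] <= 1
            assert f["entropy"] <= np.log(f["n_clusters"]) + 1e-9
            assert f["total_distance"] >= 0
            assert 0 < f["coverage"] <= 1

    def test_extraction_deterministic(self):
        trace = self._home_week(noise=10.0, seed=2)
        pd.testing.assert_frame_equal(extract_features(trace), extract_features(trace))

    def test_feature_columns_complete(self):
        feats = extract_features(self._home_week())
        assert list(feats.columns) == ["week_start", *FEATURE_NAMES, "coverage"]
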