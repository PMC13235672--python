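"""Ground-truth generator tests: determinism, defect injection, and
parameter recovery (the generator's injected effects must be visible to
the downstream extractors at their configured sizes)."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from walkscape.gps import clean_stream, segment_trips
from walkscape.physio import detect_scrs, eda_decompose, eda_smooth, hrv_windows
from walkscape.synthetic import (
    GroundTruthConfig,
    cell_features,
    generate_dataset,
    generate_physio,
    generate_ratings,
    generate_scene,
    generate_trips,
)

from conftest import make_stream  # noqa: F401 (fixture helpers)


class TestConfig:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthConfig(residual_sd=-1.0)

    def test_zero_trips_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthConfig(trips_per_participant=0)


class TestScene:
    def test_determinism(self, small_config):
        a = generate_scene(small_config)
        b = generate_scene(small_config)
        np.testing.assert_array_equal(a.ndvi, b.ndvi)
        np.testing.assert_array_equal(a.noise_lden, b.noise_lden)
        assert a.poi_points == b.poi_points
        assert a.images == b.images

    def test_degenerate_extent_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_scene(small_config, extent=(0, 0, 100, 0))

    def test_single_archetype_flat(self):
        # one archetype: only within-zone noise/field variation remains,
        # far below the spread a 4-archetype scene shows
        cfg = GroundTruthConfig(n_participants=2, trips_per_participant=2,
                                n_archetypes=1, seed=4)
        scene = generate_scene(cfg)
        between_sd = float(np.std(scene.ndvi))
        assert between_sd < 0.15
        scene4 = generate_scene(GroundTruthConfig(
            n_participants=2, trips_per_participant=2, n_archetypes=4, seed=4))
        assert between_sd < 0.6 * float(np.std(scene4.ndvi))

    def test_archetype_recovery_ari(self, small_scene):
        X = cell_features(small_scene)
        labels = KMeans(n_clusters=4, n_init=10, random_state=0).fit_predict(X)
        assert adjusted_rand_score(small_scene.archetype, labels) >= 0.9

    def test_identical_profiles_ari_zero(self):
        cfg = GroundTruthConfig(n_participants=2, trips_per_participant=2,
                                archetype_separation=0.0, seed=4)
        scene = generate_scene(cfg)
        X = cell_features(scene)
        labels = KMeans(n_clusters=4, n_init=10, random_state=0).fit_predict(X)
        assert abs(adjusted_rand_score(scene.archetype, labels)) < 0.1

    def test_image_proportions_sum_to_one(self, small_scene):
        for _, _, _, props in small_scene.images:
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_ndvi_in_range(self, small_scene):
        assert np.all(small_scene.ndvi >= -1.0) and np.all(small_scene.ndvi <= 1.0)


class TestTrips:
    def test_clean_survival_without_defects(self, small_config, small_scene):
        streams, _ = generate_trips(small_scene, small_config)
        for s in streams[:10]:
            cleaned, n = clean_stream(s)
            assert n == 0 and len(cleaned) == len(s)
            assert len(segment_trips(cleaned)) == 1

    def test_teleport_rate_one(self, small_scene):
        cfg = GroundTruthConfig(n_participants=3, trips_per_participant=3,
                                teleport_rate=1.0, seed=9)
        streams, truth = generate_trips(small_scene, cfg)
        from walkscape.gps import _haversine_arrays

        for s in streams:
            d = _haversine_arrays(s.lat[:-1], s.lon[:-1], s.lat[1:], s.lon[1:])
            assert np.sum(d > 500.0) == 2  # jump out and jump back
            cleaned, n = clean_stream(s)
            assert n == 1  # the displaced fix alone is dropped

    def test_dwell_splits_match_truth(self, small_scene):
        cfg = GroundTruthConfig(n_participants=4, trips_per_participant=3,
                                dwell_rate=1.0, seed=9,
                                trip_duration_range_s=(400.0, 600.0))
        streams, truth = generate_trips(small_scene, cfg)
        for s in streams:
            expected = truth[s.trip_id]["segments"]
            if len(expected) < 2:
                continue
            cleaned, _ = clean_stream(s)
            got = segment_trips(cleaned)
            assert len(got) == len(expected)
            for trip, (t0, t1) in zip(got, expected):
                assert abs(trip.t[0] - t0) <= 120.0
                assert abs(trip.t[-1] - t1) <= 120.0

    def test_walking_speed_plausible(self, small_config, small_scene):
        streams, _ = generate_trips(small_scene, small_config)
        s = streams[0]
        from walkscape.gps import _haversine_arrays

        d = _haversine_arrays(s.lat[:-1], s.lon[:-1], s.lat[1:], s.lon[1:])
        assert 0.5 <= np.median(d) <= 2.0  # ~1 fix/s at walking speed


class TestPhysio:
    def test_no_scrs_when_rate_zero(self, straight_trip):
        cfg = GroundTruthConfig(n_participants=2, trips_per_participant=2,
                                scr_rate=0.0, seed=5)
        rng = np.random.default_rng(0)
        s = generate_physio(straight_trip, cfg, rng)
        sm = eda_smooth(s.eda_raw, fs=s.fs_eda)
        _, phasic = eda_decompose(sm, fs=s.fs_eda)
        assert detect_scrs(phasic, fs=s.fs_eda, amp_threshold_uS=0.05) == []

    def test_rmssd_target_recovered(self, straight_trip):
        cfg = GroundTruthConfig(n_participants=2, trips_per_participant=2, seed=5)
        rng = np.random.default_rng(1)
        s = generate_physio(straight_trip, cfg, rng, target_rmssd_ms=50.0)
        windows = hrv_windows(s.ibi_t, s.ibi_ms)
        assert len(windows) >= 30
        mean_rmssd = np.mean([w.rmssd_ms for w in windows])
        assert mean_rmssd == pytest.approx(50.0, rel=0.10)

    def test_skin_temp_plausible(self, straight_trip):
        cfg = GroundTruthConfig(n_participants=2, trips_per_participant=2, seed=5)
        s = generate_physio(straight_trip, cfg, np.random.default_rng(2))
        assert 30.0 < np.mean(s.skin_temp) < 36.0

    def test_amplitude_beta_recovery(self, straight_trip):
        """Injected amplitude shift per 1-SD exposure is recoverable by
        regression of extracted mean SCR amplitude on the exposure."""
        from walkscape.physio import extract_trip_indicators
        import statsmodels.api as sm_api

        beta = 0.16
        cfg = GroundTruthConfig(n_participants=2, trips_per_participant=2, seed=5)
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 200)
        z = (z - z.mean()) / z.std()
        amps = []
        for zi in z:
            s = generate_physio(straight_trip, cfg, rng, amp_shift_uS=beta * zi)
            amps.append(extract_trip_indicators(s)["scr_amp_mean"])
        fit = sm_api.OLS(np.asarray(amps), sm_api.add_constant(z)).fit()
        assert abs(fit.params[1] - beta) <= 2 * fit.bse[1]


class TestRatings:
    def _table(self, n=400, n_participants=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"participant_id": np.repeat(
                [f"P{i}" for i in range(n_participants)], n // n_participants),
             "img_curbs": rng.normal(0.05, 0.02, n),
             "ndvi_mean": rng.normal(0.3, 0.1, n)}
        )

    def test_degenerate_all_grand_mean(self):
        cfg = GroundTruthConfig(rating_betas={}, random_intercept_sd=0.0,
                                residual_sd=0.0, seed=1)
        ratings, _ = generate_ratings(self._table(), cfg)
        assert (ratings["trip_feeling_env"] == 3).all()
        assert (ratings["unwell_well"] == 4).all()  # 3.5 rounds half-to-even

    def test_scale_bounds_respected(self):
        cfg = GroundTruthConfig(
            rating_betas={"img_curbs": 1.5}, random_intercept_sd=2.0,
            residual_sd=3.0, seed=2)
        table = self._table(n=100_000, n_participants=100)
        ratings, _ = generate_ratings(table, cfg)
        assert ratings["trip_feeling_env"].between(0, 5).all()
        for c in ("unwell_well", "agitated_calm", "tired_awake"):
            assert ratings[c].between(1, 6).all()

    def test_unknown_predictor_rejected(self):
        cfg = GroundTruthConfig(rating_betas={"no_such_exposure": 0.1})
        with pytest.raises(ValueError, match="unknown predictors"):
            generate_ratings(self._table(), cfg)

    def test_flat_betas_apply_to_all_outcomes(self):
        cfg = GroundTruthConfig(rating_betas={"img_curbs": 0.5},
                                random_intercept_sd=0.0, residual_sd=0.0, seed=3)
        table = self._table(n=2000, n_participants=20)
        ratings, _ = generate_ratings(table, cfg)
        z = (table["img_curbs"] - table["img_curbs"].mean()) / table["img_curbs"].std(ddof=0)
        for c in ratings.columns:
            r = np.corrcoef(z, ratings[c])[0, 1]
            assert r > 0.5


class TestRatingEffectRecovery:
    def test_h1_recovers_injected_curb_effect(self):
        """The joint H1 mixed model recovers the injected standardized
        curb and tourism effects within 2 SE."""
        from walkscape.inference import run_h1

        cfg = GroundTruthConfig(n_participants=45, trips_per_participant=12,
                                seed=11)
        ds = generate_dataset(cfg, compute_physio=False)
        h1 = run_h1(ds.trip_table).set_index(["outcome", "predictor"])
        checks = [("unwell_well", "img_curbs", 0.078),
                  ("agitated_calm", "img_curbs", 0.092),
                  ("tired_awake", "poi_tourism", 0.127)]
        for outcome, pred, truth in checks:
            row = h1.loc[(outcome, pred)]
            assert abs(row["beta"] - truth) <= 2 * row["se"], (outcome, pred)


class TestDataset:
    def test_table_determinism(self, small_config, small_dataset):
        again = generate_dataset(small_config)
        pd.testing.assert_frame_equal(small_dataset.trip_table, again.trip_table)

    def test_row_count_and_schema(self, small_dataset):
        t = small_dataset.trip_table
        assert len(t) == 8 * 5
        from walkscape.physio import PHYSIO_INDICATORS
        from walkscape.inference import RATING_COLUMNS

        for col in (*PHYSIO_INDICATORS, *RATING_COLUMNS, "ndvi_mean", "t_max"):
            assert col in t.columns

    def test_injected_amplitude_effect_visible(self, small_dataset):
        t = small_dataset.trip_table
        r = np.corrcoef(t["scr_amp_mean"], t["noise_lden_mean"])[0, 1]
        assert r > 0.2  # noise beta 0.18 µS/SD is visible at n=40
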