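"""Region filter, track regularization, MEC windows, range GLM, buffers."""

import numpy as np
import pandas as pd
import pytest

from msfr.foraging_range import (
    build_mec_windows,
    filter_region,
    fit_range_glm,
    predict_buffer,
    regularize_track,
    windows_for_animals,
)
from msfr.geometry import minimum_enclosing_circle
from msfr.synthetic_data import default_ground_truth, generate_tracks


def track_frame(points, animal="a1", age="adult", sex="F", start="2010-01-01"):
    ts = pd.date_range(start, periods=len(points), freq="6h")
    lon, lat = zip(*points)
    return pd.DataFrame({"animal_id": animal, "timestamp": ts, "lon": lon, "lat": lat,
                         "age_class": age, "sex": sex})


class TestRegionFilter:
    def test_quoted_thresholds(self):
        t = track_frame([(9.50, 57.40), (9.50, 57.20), (9.00, 57.20)])
        out = filter_region(t)
        kept = set(zip(out["lon"], out["lat"]))
        assert (9.50, 57.40) in kept      # north of the latitude cut
        assert (9.50, 57.20) not in kept  # south AND east: excluded
        assert (9.00, 57.20) in kept      # south but west of the longitude cut

    def test_empty_track_passthrough(self):
        t = pd.DataFrame({"animal_id": [], "timestamp": [], "lon": [], "lat": []})
        assert len(filter_region(t)) == 0

    def test_matches_direct_predicate_on_random_points(self, rng):
        lon = rng.uniform(8.0, 11.0, 1000)
        lat = rng.uniform(56.0, 58.5, 1000)
        t = track_frame(list(zip(lon, lat)))
        out = filter_region(t)
        expect = ~((lat < 57.30) & (lon > 9.37))
        assert len(out) == int(expect.sum())
        np.testing.assert_array_equal(out["lon"].to_numpy(), lon[expect])


class TestRegularization:
    def test_two_points_24h_apart_give_five_positions(self):
        t = track_frame([(4.0, 53.0), (4.2, 53.2)])
        t["timestamp"] = pd.to_datetime(["2010-01-01 00:00", "2010-01-02 00:00"])
        reg = regularize_track(t, step_hours=6.0)
        assert len(reg) == 5

    def test_already_regular_track_unchanged(self):
        t = track_frame([(4.0, 53.0), (4.1, 53.1), (4.2, 53.2)])
        reg = regularize_track(t, step_hours=6.0)
        np.testing.assert_allclose(reg["lon"].to_numpy(), t["lon"].to_numpy(), atol=1e-9)
        np.testing.assert_allclose(reg["lat"].to_numpy(), t["lat"].to_numpy(), atol=1e-9)

    def test_interpolation_stays_on_chord(self):
        t = track_frame([(3.0, 53.0), (5.0, 54.0)])
        t["timestamp"] = pd.to_datetime(["2010-01-01 00:00", "2010-01-03 00:00"])
        reg = regularize_track(t, step_hours=6.0)
        # cross-track deviation in projected coordinates is zero
        p0 = reg[["x_km", "y_km"]].iloc[0].to_numpy()
        p1 = reg[["x_km", "y_km"]].iloc[-1].to_numpy()
        d = p1 - p0
        d /= np.linalg.norm(d)
        rel = reg[["x_km", "y_km"]].to_numpy() - p0
        cross = rel[:, 0] * d[1] - rel[:, 1] * d[0]
        assert np.max(np.abs(cross)) < 1e-9

    def test_long_gap_splits_segments(self):
        t = track_frame([(4.0, 53.0), (4.1, 53.1)])
        t2 = track_frame([(4.5, 53.5), (4.6, 53.6)], start="2010-02-01")
        track = pd.concat([t, t2], ignore_index=True)
        reg = regularize_track(track, step_hours=6.0, max_gap_hours=48.0)
        assert reg["segment"].nunique() == 2

    def test_single_position_rejected(self):
        with pytest.raises(ValueError):
            regularize_track(track_frame([(4.0, 53.0)]))


class TestMECWindows:
    def test_eight_day_track_two_day_windows(self):
        pts = [(4.0 + 0.01 * i, 53.0) for i in range(33)]  # 8 days at 6 h
        reg = regularize_track(track_frame(pts))
        w = build_mec_windows(reg, 2)
        assert len(w) == 4

    def test_stationary_animal_zero_diameters(self):
        pts = [(4.0, 53.0)] * 9
        t = track_frame(pts)
        reg = regularize_track(t)
        w = build_mec_windows(reg, 2)
        assert (w["diameter"] == 0).all()

    def test_diameters_match_direct_mec(self, rng):
        pts = [(4.0 + 0.05 * rng.standard_normal(), 53.0 + 0.05 * rng.standard_normal())
               for _ in range(17)]
        reg = regularize_track(track_frame(pts))
        w = build_mec_windows(reg, 2)
        per = int(2 * 24 / 6)
        for k, row in w.reset_index().iterrows():
            seg = reg.iloc[k * per:(k + 1) * per][["x_km", "y_km"]].to_numpy()
            _, r = minimum_enclosing_circle(seg)
            assert row["diameter"] == pytest.approx(2 * r, abs=1e-9)

    def test_window_points_inside_circle(self, rng):
        pts = [(4.0 + 0.03 * rng.standard_normal(), 53.0 + 0.03 * rng.standard_normal())
               for _ in range(33)]
        reg = regularize_track(track_frame(pts))
        per = int(2 * 24 / 6)
        w = build_mec_windows(reg, 2)
        for k, row in w.reset_index().iterrows():
            seg = reg.iloc[k * per:(k + 1) * per][["x_km", "y_km"]].to_numpy()
            d = np.hypot(seg[:, 0] - row["center_x"], seg[:, 1] - row["center_y"])
            assert np.all(d <= row["diameter"] / 2 + 1e-6)

    def test_invalid_timeframe_rejected(self):
        reg = regularize_track(track_frame([(4.0, 53.0), (4.1, 53.1)]))
        with pytest.raises(ValueError):
            build_mec_windows(reg, 3)


@pytest.fixture(scope="module")
def fitted_model():
    gt = default_ground_truth(seed=30)
    tracks = generate_tracks(gt, n_animals=40, days=40, rng=np.random.default_rng(31))
    windows = windows_for_animals(tracks)
    return gt, windows, fit_range_glm(windows)


class TestRangeGLM:
    def test_needs_enough_windows(self):
        w = pd.DataFrame({"diameter": [10.0] * 5, "timeframe": ["2"] * 5,
                          "age_class": ["adult"] * 5, "sex": ["F"] * 5, "quarter": ["Q1"] * 5})
        with pytest.raises(ValueError):
            fit_range_glm(w)

    def test_selected_aic_is_minimum(self, fitted_model):
        _, _, model = fitted_model
        assert model.fit.aic == pytest.approx(model.search.candidates["aic"].min())

    def test_timeframe_effect_positive_and_ordered(self, fitted_model):
        """Longer timeframes must predict larger foraging ranges."""
        _, _, model = fitted_model
        d = [model.predict_diameter(tf, "adult", "F", "Q1") for tf in (2, 4, 6, 8)]
        assert all(b > a for a, b in zip(d, d[1:]))

    def test_prediction_grid_layout(self, fitted_model):
        _, _, model = fitted_model
        grid = model.prediction_grid()
        assert len(grid) == 16  # 4 timeframes x 4 quarters
        assert list(grid.columns) == ["timeframe", "quarter", "adult_F", "adult_M",
                                      "juvenile_F", "juvenile_M"]


class TestPredictBuffer:
    def test_radius_equals_predicted_diameter(self, fitted_model):
        """The buffer radius is the predicted *diameter* — the deliberate
        twofold inflation for the unknown direction of travel — and no
        further doubling is applied."""
        _, _, model = fitted_model
        s = pd.Series({"id": 9, "lon": 4.3, "lat": 52.9, "age_class": "adult",
                       "sex": "F", "date": pd.Timestamp("2012-02-01")})
        buf = predict_buffer(model, s, 4)
        assert buf.radius_km == pytest.approx(model.predict_diameter(4, "adult", "F", "Q1"))
        assert buf.timeframe_days == 4

    def test_unseen_covariate_level_raises(self, fitted_model):
        _, _, model = fitted_model
        s = pd.Series({"id": 9, "lon": 4.3, "lat": 52.9, "age_class": "calf",
                       "sex": "F", "date": pd.Timestamp("2012-02-01")})
        with pytest.raises(ValueError):
            predict_buffer(model, s, 4)

    def test_monotone_in_timeframe(self, fitted_model):
        _, _, model = fitted_model
        s = pd.Series({"id": 9, "lon": 4.3, "lat": 52.9, "age_class": "juvenile",
                       "sex": "M", "date": pd.Timestamp("2012-08-01")})
        radii = [predict_buffer(model, s, tf).radius_km for tf in (2, 4, 6, 8)]
        assert all(b > a for a, b in zip(radii, radii[1:]))


def test_glm_recovers_track_covariate_ordering(fitted_model):
    """Males and juveniles are generated with smaller step scales, so the
    fitted model should predict smaller ranges for them."""
    _, _, model = fitted_model
    assert model.predict_diameter(4, "adult", "F", "Q1") > \
        model.predict_diameter(4, "juvenile", "M", "Q1")
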