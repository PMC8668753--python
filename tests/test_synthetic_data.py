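"""Generators: determinism, generative laws, functional-response consistency."""

import numpy as np
import pandas as pd
import pytest

from msfr.geometry import AzimuthalEquidistant
from msfr.synthetic_data import (
    GaussianBump,
    GroundTruth,
    StudyRegion,
    default_ground_truth,
    generate_prey_surveys,
    generate_strandings_and_stomachs,
    generate_tracks,
    true_availability,
)


class TestRegion:
    def test_sea_mask_nonempty_and_coastline_consistent(self):
        region = StudyRegion()
        grid = region.grid()
        assert grid["sea"].any() and (~grid["sea"]).any()
        # points just west of the coastline are sea, just east are land
        lat = 53.0
        lon_c = float(region.coast_lon(lat))
        assert region.is_sea(lon_c - 0.05, lat)
        assert not region.is_sea(lon_c + 0.05, lat)

    def test_empty_sea_mask_raises(self):
        region = StudyRegion(coast_offset=-10.0)  # everything is land
        with pytest.raises(ValueError):
            region.grid()


class TestPreySurveys:
    def test_determinism_under_seed(self, ground_truth):
        h1 = generate_prey_surveys(ground_truth, n_hauls=40,
                                   rng=np.random.default_rng(5))
        h2 = generate_prey_surveys(ground_truth, n_hauls=40,
                                   rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(h1, h2)

    def test_all_hauls_at_sea(self, ground_truth):
        h = generate_prey_surveys(ground_truth, n_hauls=150, rng=np.random.default_rng(1))
        assert ground_truth.region.is_sea(h["lon"].to_numpy(), h["lat"].to_numpy()).all()

    def test_lengths_below_consumability_limit(self, ground_truth):
        h = generate_prey_surveys(ground_truth, n_hauls=30, rng=np.random.default_rng(2))
        assert (h["length_class_lower"] < 400).all()

    def test_degenerate_surface_zero_cpue(self):
        gt = default_ground_truth(seed=3, field_baseline=0.0)
        for sp in gt.species:
            gt.prey_field_params[sp] = {k: [] for k in gt.prey_field_params[sp]}
        h = generate_prey_surveys(gt, n_hauls=25, rng=np.random.default_rng(0))
        assert (h["cpue"] == 0).all()

    def test_doubling_amplitude_doubles_mean_cpue(self):
        """Monte-Carlo check of the stated generative law at n_hauls=5000."""
        means = {}
        for scale in (1.0, 2.0):
            gt = default_ground_truth(seed=9)
            for key, bumps in gt.prey_field_params["whiting"].items():
                gt.prey_field_params["whiting"][key] = [
                    GaussianBump(b.lon, b.lat, b.sigma_km, scale * b.amplitude) for b in bumps
                ]
            gt.field_baseline = 0.0
            h = generate_prey_surveys(gt, n_hauls=5000, rng=np.random.default_rng(4))
            w = h[h["species"] == "whiting"]
            means[scale] = w.groupby("haul_id")["cpue"].sum().mean()
        ratio = means[2.0] / means[1.0]
        assert ratio == pytest.approx(2.0, rel=0.1)


class TestTracks:
    def test_determinism(self, ground_truth):
        t1 = generate_tracks(ground_truth, n_animals=4, days=10,
                             rng=np.random.default_rng(6))
        t2 = generate_tracks(ground_truth, n_animals=4, days=10,
                             rng=np.random.default_rng(6))
        pd.testing.assert_frame_equal(t1, t2)

    def test_positions_confined_to_sea(self, ground_truth):
        t = generate_tracks(ground_truth, n_animals=5, days=15, rng=np.random.default_rng(7))
        assert ground_truth.region.is_sea(t["lon"].to_numpy(), t["lat"].to_numpy()).all()

    def test_zero_step_scale_stationary(self, ground_truth):
        t = generate_tracks(ground_truth, n_animals=2, days=5, base_step_km=0.0,
                            rng=np.random.default_rng(8))
        for _, grp in t.groupby("animal_id"):
            assert grp["lon"].nunique() == 1 and grp["lat"].nunique() == 1

    def test_larger_step_scale_larger_mec(self, ground_truth):
        """Ordering check: doubling the step scale increases mean 2-day MEC."""
        from msfr.foraging_range import build_mec_windows, regularize_track

        def mean_mec(step):
            t = generate_tracks(ground_truth, n_animals=25, days=8, base_step_km=step,
                                rng=np.random.default_rng(11))
            diams = []
            for _, grp in t.groupby("animal_id"):
                reg = regularize_track(grp)
                w = build_mec_windows(reg, 2)
                diams.extend(w["diameter"])
            return np.mean(diams)

        assert mean_mec(8.0) > mean_mec(2.0)


class TestStrandingsAndStomachs:
    def test_determinism(self, ground_truth):
        s1, o1 = generate_strandings_and_stomachs(ground_truth, 20,
                                                  rng=np.random.default_rng(9))
        s2, o2 = generate_strandings_and_stomachs(ground_truth, 20,
                                                  rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(o1, o2)

    def test_decomposition_codes_span_filter(self, small_tables):
        strandings, _ = small_tables
        assert set(strandings["decomposition_code"]) <= {1, 2, 3, 4, 5}
        assert (strandings["decomposition_code"] >= 4).any()
        assert (strandings["decomposition_code"] < 4).any()

    def test_availability_rescaled_to_100(self, small_tables):
        strandings, _ = small_tables
        avail_cols = [c for c in strandings.columns if c.startswith("avail_")]
        assert strandings[avail_cols].to_numpy().max() == pytest.approx(100.0)

    def test_diet_shares_follow_functional_response(self):
        """Mean generated mass shares over many strandings with identical
        buffers match the generative model proportions within 3 MC SEs."""
        gt = default_ground_truth(seed=13)
        # identical buffers: force one location/season/year via a tiny region
        # trick - instead verify per-stranding against its own availability
        rng = np.random.default_rng(14)
        strandings, otoliths = generate_strandings_and_stomachs(gt, 1000, rng=rng)
        # reconstruct true masses (exact inversion)
        from msfr.diet_composition import reconstruct_prey_mass

        allom = {s: (p["oto_a"], p["oto_b"]) for s, p in gt.lw_params.items()}
        masses = reconstruct_prey_mass(otoliths, gt.grade_factors, allom)
        per = masses.groupby(["stranding_id", "species"])["prey_mass_g"].sum().unstack(fill_value=0)
        per = per.reindex(columns=gt.species, fill_value=0.0)
        shares = per.div(per.sum(axis=1), axis=0)
        a = np.array([gt.attack_rates[s] for s in gt.species])
        B = strandings.set_index("id")[[f"avail_{s}" for s in gt.species]].to_numpy()
        num = a[None, :] * B**gt.shape_m
        expected = num / num.sum(axis=1, keepdims=True)
        expected = pd.DataFrame(expected, index=strandings["id"], columns=gt.species)
        # pooled composition (total mass over all strandings): the ratio
        # estimator whose expectation is the mean functional-response
        # proportion; per-stranding mean-of-ratios carries a Jensen bias
        pooled = per.sum(axis=0) / per.to_numpy().sum()
        expected_pooled = expected.loc[shares.index].mean(axis=0)
        rng2 = np.random.default_rng(1)
        M = per.to_numpy()
        boots = np.empty((200, len(gt.species)))
        for b in range(200):
            pick = rng2.integers(0, len(M), len(M))
            boots[b] = M[pick].sum(axis=0) / M[pick].sum()
        se = boots.std(axis=0)
        for j, sp in enumerate(gt.species):
            assert abs(pooled[sp] - expected_pooled[sp]) < 3 * max(se[j], 1e-4), sp

    def test_all_zero_availability_raises(self):
        gt = default_ground_truth(seed=15, field_baseline=0.0, other_index=0.0)
        for sp in gt.species:
            gt.prey_field_params[sp] = {k: [] for k in gt.prey_field_params[sp]}
        gt.sandeel_ssb = {y: 0.0 for y in gt.years}
        with pytest.raises(ValueError):
            generate_strandings_and_stomachs(gt, 5, rng=np.random.default_rng(0))


class TestGroundTruthValidation:
    def test_reference_attack_rate_must_be_one(self):
        with pytest.raises(ValueError):
            GroundTruth(attack_rates={"sandeel": 2.0, "cod": 0.5})

    def test_shape_below_one_rejected(self):
        with pytest.raises(ValueError):
            default_ground_truth(shape_m=0.5)

    def test_json_round_trip_writes(self, ground_truth, tmp_path):
        ground_truth.to_json(tmp_path / "gt.json")
        import json

        blob = json.loads((tmp_path / "gt.json").read_text())
        assert blob["shape_m"] == ground_truth.shape_m
        assert set(blob["attack_rates"]) == set(ground_truth.attack_rates)
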