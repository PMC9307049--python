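"""Synthetic-data generators: truth attachment, seeding, planted effects."""

import numpy as np
import pytest

from mycouptake.chem import class_statistics, classify_phases, distance_classes
from mycouptake.growth import GrowthParams, evaluate_at
from mycouptake.inference import fit_uptake
from mycouptake.skeleton import compute_metrics, voxel_skeleton_to_graph
from mycouptake.synthetic import (
    WEEK_S,
    gen_length_density_obs,
    gen_p_profile,
    gen_skeleton,
    gen_xanes,
    gen_xrf_maps,
)
from mycouptake.uptake import UptakeParams


class TestLengthDensityObs:
    def test_zero_noise_equals_model(self, study_params):
        obs, truth = gen_length_density_obs(study_params, noise_level=0.0, seed=0)
        np.testing.assert_array_equal(obs.values, evaluate_at(study_params, obs))
        assert truth.params["growth"]["k"] == study_params.k

    def test_same_seed_reproduces(self, study_params):
        a, _ = gen_length_density_obs(study_params, seed=42)
        b, _ = gen_length_density_obs(study_params, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        c, _ = gen_length_density_obs(study_params, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_lognormal_noise_cv_calibrated(self, study_params):
        obs, _ = gen_length_density_obs(
            study_params,
            positions_cm=[1.35],
            times_s=[2 * WEEK_S],
            n_replicates=10_000,
            noise_level=0.10,
            seed=7,
        )
        cv = obs.values.std() / obs.values.mean()
        assert cv == pytest.approx(0.10, abs=0.005)

    def test_default_design_is_the_study_design(self, study_params):
        obs, _ = gen_length_density_obs(study_params, seed=0)
        assert sorted(set(obs.positions)) == [1.35, 2.85, 4.35]
        assert sorted(set(obs.times)) == [2 * WEEK_S, 4 * WEEK_S]
        assert len(obs) == 18  # 3 positions x 2 times x 3 replicates


class TestSkeletonGenerator:
    def test_straight_mode_matches_planted_launch(self):
        ds = gen_skeleton(
            length_um=200,
            radius_um=80,
            voxel_size_um=2.0,
            n_tips=4,
            persistence=1.0,
            branch_prob=0.0,
            stop_prob=0.0,
            seed=1,
        )
        m = compute_metrics(ds.graph, (1, 0, 0), 1e6)
        np.testing.assert_allclose(m.tortuosity, 1.0)
        np.testing.assert_allclose(m.angle_deg, 0.0, atol=1e-9)

    def test_seed_reproducibility_of_volume(self):
        a = gen_skeleton(length_um=150, radius_um=60, voxel_size_um=3.0, seed=5)
        b = gen_skeleton(length_um=150, radius_um=60, voxel_size_um=3.0, seed=5)
        np.testing.assert_array_equal(a.volume, b.volume)

    def test_presets_contrast_in_branching(self):
        bpc = {"inoculated": [], "control": []}
        for preset in bpc:
            for seed in range(15):
                ds = gen_skeleton(
                    length_um=400,
                    radius_um=150,
                    voxel_size_um=4.0,
                    preset=preset,
                    n_tips=5,
                    voxelize=False,
                    seed=seed,
                )
                bpc[preset].append(ds.graph.n_branches / ds.graph.n_clusters)
        assert np.mean(bpc["control"]) > 2 * np.mean(bpc["inoculated"])

    def test_voxel_metrics_match_polyline_truth(self):
        ds = gen_skeleton(
            length_um=200,
            radius_um=80,
            voxel_size_um=2.0,
            n_tips=4,
            persistence=0.97,
            branch_prob=0.0,
            stop_prob=0.0,
            seed=2,
        )
        g = voxel_skeleton_to_graph(ds.volume, 2.0)
        assert g.n_branches == ds.graph.n_branches
        assert g.total_length == pytest.approx(ds.graph.total_length, rel=0.10)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            gen_skeleton(length_um=0.0)


class TestXRFGenerator:
    def test_planted_phases_recovered_exactly(self):
        ds = gen_xrf_maps(shape=(96, 96), seed=11)
        thr = ds.truth.params
        labels = classify_phases(
            ds.xrf_map, thr["air_threshold_total"], thr["si_threshold"]
        )
        np.testing.assert_array_equal(labels.labels, ds.phases.labels)

    def test_seed_reproducibility(self):
        a = gen_xrf_maps(shape=(64, 64), seed=3)
        b = gen_xrf_maps(shape=(64, 64), seed=3)
        for el in a.xrf_map.elements:
            np.testing.assert_array_equal(a.xrf_map.elements[el], b.xrf_map.elements[el])

    def test_no_coupling_mostly_insignificant(self):
        hits = 0
        for seed in range(10):
            ds = gen_xrf_maps(shape=(128, 128), p_coupling=0.0, seed=200 + seed)
            thr = ds.truth.params
            phases = classify_phases(
                ds.xrf_map, thr["air_threshold_total"], thr["si_threshold"]
            )
            st = class_statistics(
                ds.xrf_map, phases, distance_classes(ds.distance), "P"
            )
            hits += st.t_p < 0.05
        assert hits <= 2

    def test_default_close_far_ratio_near_1p24(self):
        ratios = []
        for seed in range(5):
            ds = gen_xrf_maps(seed=seed)
            thr = ds.truth.params
            phases = classify_phases(
                ds.xrf_map, thr["air_threshold_total"], thr["si_threshold"]
            )
            st = class_statistics(
                ds.xrf_map, phases, distance_classes(ds.distance), "P"
            )
            ratios.append(st.close_mean / st.far_mean)
        assert np.mean(ratios) == pytest.approx(1.24, abs=0.05)


class TestXanesGenerator:
    def test_noise_free_single_component_equals_standard(self):
        spec, lib, _ = gen_xanes({"thiol": 1.0}, snr=np.inf)
        np.testing.assert_array_equal(spec.intensities, lib["thiol"].intensities)

    def test_seed_reproducibility(self):
        a, _, _ = gen_xanes({"thiol": 0.5, "sulfate": 0.5}, snr=50, seed=9)
        b, _, _ = gen_xanes({"thiol": 0.5, "sulfate": 0.5}, snr=50, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            gen_xanes({"thiol": 0.5})
        with pytest.raises(ValueError):
            gen_xanes({"thiol": 1.5, "sulfate": -0.5})

    def test_s_peak_positions(self):
        _, lib, _ = gen_xanes({"thiol": 1.0}, snr=np.inf)
        for name, peak_ev in [("thiol", 2473.0), ("sulfonate", 2480.5), ("sulfate", 2482.0)]:
            spec = lib[name]
            # white line sits at the documented energy
            assert spec.energies[np.argmax(spec.intensities)] == pytest.approx(
                peak_ev, abs=0.3
            )


class TestPProfileGenerator:
    def test_no_uptake_profile_is_flat(self, study_params):
        up = UptakeParams(lambda_h=0.0, f_max=0.0)
        profile, _ = gen_p_profile(up, study_params, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(profile["c_rel"], 1.0, atol=1e-12)

    def test_round_trip_lambda_recovery(self, study_params):
        up = UptakeParams(lambda_h=3.26e-6)
        profile, truth = gen_p_profile(up, study_params, noise_sd=0.0, seed=0)
        from mycouptake.growth import solve_growth_closed_form

        rho = solve_growth_closed_form(
            study_params, np.linspace(0, 1.5, 201), np.linspace(0, 4 * WEEK_S, 81)
        )
        fit = fit_uptake(
            profile, rho, UptakeParams(), t_final=4 * WEEK_S, domain_length=1.5
        )
        assert fit.estimates["lambda_h"] == pytest.approx(3.26e-6, rel=0.01)
        assert truth.params["lambda_h"] == 3.26e-6

    def test_seed_reproducibility(self, study_params):
        up = UptakeParams(lambda_h=1e-6)
        a, _ = gen_p_profile(up, study_params, noise_sd=0.02, seed=3)
        b, _ = gen_p_profile(up, study_params, noise_sd=0.02, seed=3)
        np.testing.assert_array_equal(a["c_rel"], b["c_rel"])


class TestTruthSerialisation:
    def test_truth_round_trips_to_json(self, tmp_path, study_params):
        _, truth = gen_length_density_obs(study_params, seed=1)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["seed"] == 1
        assert payload["generator"] == "length_density_obs"
        assert "version" in payload
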