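"""Distance-transform chemometrics: phases, distance classes, statistics."""

import numpy as np
import pytest
from scipy import stats

from mycouptake.chem import (
    AIR,
    CLOSE,
    FAR,
    MIXED,
    NEITHER,
    PRIMARY,
    DistancePlane,
    EmptyMaskError,
    PhaseLabels,
    XRFMap,
    class_statistics,
    classify_phases,
    distance_classes,
    distance_transform_3d,
    elemental_classes,
    register_plane,
)


def brute_force_distance(mask, voxel_size):
    """O(N*M) all-pairs oracle."""
    fg = np.argwhere(mask)
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        d = np.linalg.norm(fg - np.asarray(idx), axis=1).min()
        out[idx] = d * voxel_size
    return out


class TestDistanceTransform:
    def test_single_voxel_source_formula(self):
        mask = np.zeros((5, 6, 7), bool)
        mask[0, 0, 0] = True
        d = distance_transform_3d(mask, voxel_size=2.0)
        i, j, k = 3, 4, 5
        assert d[i, j, k] == pytest.approx(2.0 * np.sqrt(i**2 + j**2 + k**2))
        assert d[0, 0, 0] == 0.0

    def test_all_foreground_is_zero(self):
        d = distance_transform_3d(np.ones((4, 4, 4), bool), 1.6)
        assert np.all(d == 0)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(EmptyMaskError):
            distance_transform_3d(np.zeros((3, 3, 3), bool))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12, 12)) < 0.02
        if not mask.any():
            mask[0, 0, 0] = True
        d = distance_transform_3d(mask, voxel_size=1.6)
        np.testing.assert_allclose(d, brute_force_distance(mask, 1.6), atol=1e-9)


def make_map(p=None, al=None, s=None, si=None, shape=(10, 10), pixel=10.0):
    def arr(v):
        return np.full(shape, float(v)) if np.isscalar(v) else np.asarray(v, float)

    return XRFMap(
        elements={
            "P": arr(8000.0 if p is None else p),
            "Al": arr(3000.0 if al is None else al),
            "S": arr(600.0 if s is None else s),
            "Si": arr(500.0 if si is None else si),
        },
        pixel_size_um=pixel,
    )


class TestPhases:
    def test_planted_geometry_recovered(self):
        si = np.full((10, 10), 500.0)
        si[:3] = 5e4  # grains
        p = np.full((10, 10), 8000.0)
        p[8:] = 10.0  # air rows: every channel near zero
        al = np.full((10, 10), 3000.0)
        al[8:] = 10.0
        s = np.full((10, 10), 600.0)
        s[8:] = 5.0
        si[8:] = 20.0
        xrf = make_map(p=p, al=al, s=s, si=si)
        labels = classify_phases(xrf, air_threshold_total=1000.0, si_threshold=2.5e4)
        assert np.all(labels.labels[:3] == PRIMARY)
        assert np.all(labels.labels[8:] == AIR)
        assert np.all(labels.labels[3:8] == MIXED)

    def test_all_zero_map_is_all_air(self):
        xrf = make_map(p=0.0, al=0.0, s=0.0, si=0.0)
        labels = classify_phases(xrf, 1000.0, 2.5e4)
        assert np.all(labels.labels == AIR)

    def test_all_high_si_leaves_no_mixed(self):
        xrf = make_map(si=1e5)
        labels = classify_phases(xrf, 1000.0, 2.5e4)
        assert np.all(labels.labels == PRIMARY)
        dist = DistancePlane(np.zeros((10, 10)))
        classes = distance_classes(dist)
        with pytest.raises(ValueError, match="close"):
            class_statistics(xrf, labels, classes, "P")


class TestDistanceClasses:
    def test_threshold_tie_rules(self):
        d = DistancePlane(np.array([[49.9, 50.0, 125.0, 200.0, 250.0]]))
        labels = distance_classes(d)
        assert labels[0, 0] == CLOSE
        assert labels[0, 1] == CLOSE  # inclusive at 50
        assert labels[0, 2] == NEITHER
        assert labels[0, 3] == NEITHER  # 'further than 200' is strict
        assert labels[0, 4] == FAR

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            distance_classes(DistancePlane(np.zeros((2, 2))), close_um=300, far_um=200)


class TestClassStatistics:
    def test_identical_samples_give_zero_statistics(self):
        vals = np.tile(np.arange(10.0), (10, 1))
        xrf = make_map(p=vals)
        phases = PhaseLabels(np.full((10, 10), MIXED))
        classes = np.full((10, 10), NEITHER, np.int8)
        classes[:5] = CLOSE
        classes[5:] = FAR
        st = class_statistics(xrf, phases, classes, "P")
        assert st.t_stat == 0.0 and st.ks_stat == 0.0
        assert st.t_p == 1.0 and st.ks_p == 1.0

    def test_planted_elevation_detected(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(np.log(8000.0), 0.1, (40, 40))
        classes = np.full((40, 40), FAR, np.int8)
        classes[:20] = CLOSE
        p = base.copy()
        p[:20] *= 1.25
        xrf = make_map(p=p, shape=(40, 40))
        phases = PhaseLabels(np.full((40, 40), MIXED))
        st = class_statistics(xrf, phases, classes, "P")
        assert st.close_mean > st.far_mean
        assert st.t_p < 0.05

    def test_histograms_sum_to_one(self):
        rng = np.random.default_rng(1)
        xrf = make_map(p=rng.normal(8000, 500, (20, 20)), shape=(20, 20))
        phases = PhaseLabels(np.full((20, 20), MIXED))
        classes = np.where(np.arange(400).reshape(20, 20) % 2 == 0, CLOSE, FAR).astype(np.int8)
        st = class_statistics(xrf, phases, classes, "P", bin_width=250.0)
        assert st.close_hist.sum() == pytest.approx(1.0)
        assert st.far_hist.sum() == pytest.approx(1.0)

    def test_undersized_class_is_an_error(self):
        xrf = make_map()
        phases = PhaseLabels(np.full((10, 10), MIXED))
        classes = np.full((10, 10), FAR, np.int8)
        classes[0, 0] = CLOSE
        with pytest.raises(ValueError, match="close"):
            class_statistics(xrf, phases, classes, "P")

    def test_label_shuffling_yields_uniform_p(self):
        """Permutation sanity: under the null, t-test p-values are uniform."""
        rng = np.random.default_rng(7)
        values = rng.normal(0.0, 1.0, 400)
        pvals = []
        for _ in range(500):
            perm = rng.permutation(400)
            a, b = values[perm[:200]], values[perm[200:]]
            pvals.append(stats.ttest_ind(a, b).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestElementalClasses:
    def test_hand_enumerated_fixture(self):
        # 4x4 map: distances and P/Al planted so class membership is
        # enumerable by hand
        d = np.array(
            [
                [10.0, 10.0, 300.0, 300.0],
                [10.0, 40.0, 300.0, 700.0],
                [40.0, 40.0, 700.0, 700.0],
                [40.0, 10.0, 150.0, 150.0],
            ]
        )
        p = np.where(d < 200, 12000.0, 6000.0)  # high P tracks closeness
        p[3, 2] = 12000.0
        p[3, 3] = 12000.0
        al = np.full((4, 4), 1000.0)
        al[:, 3] = 9000.0  # one high-Al column
        xrf = make_map(p=p, al=al, shape=(4, 4))
        phases = PhaseLabels(np.full((4, 4), MIXED))
        out = elemental_classes(
            xrf,
            phases,
            DistancePlane(d),
            thresholds={"P": 9000.0, "Al": 5000.0, "S": 1e9, "Si": 1e9},
            pairs=(("P", "Al"),),
        )
        lo = out["classes"]["highP_lowAl"]
        hi = out["classes"]["highP_highAl"]
        # high P pixels: the eight with d<200 in cols 0-2 plus (3,2),(3,3)
        assert lo["count"] == 9
        assert hi["count"] == 1  # only (3,3): high P and high Al
        expect_lo = np.mean([10, 10, 10, 40, 40, 40, 40, 10, 150])
        assert lo["mean_distance_um"] == pytest.approx(expect_lo)
        assert hi["mean_distance_um"] == pytest.approx(150.0)
        assert lo["fraction_within_100um"] == pytest.approx(8 / 9)

    def test_from_close_means_matches_direct_comparison(self):
        rng = np.random.default_rng(5)
        p = rng.lognormal(np.log(8000.0), 0.2, (30, 30))
        d = rng.uniform(0, 400, (30, 30))
        xrf = make_map(p=p, shape=(30, 30))
        phases = PhaseLabels(np.full((30, 30), MIXED))
        out = elemental_classes(xrf, phases, DistancePlane(d), pairs=(("P", "Al"),))
        thr = out["thresholds"]["P"]
        assert thr == pytest.approx(p[d <= 50.0].mean())
        n_high = out["classes"]["highP_lowAl"]["count"] + out["classes"]["highP_highAl"]["count"]
        assert n_high == int((p > thr).sum())

    def test_empty_class_reported_not_nan(self):
        p = np.full((5, 5), 12000.0)
        al = np.full((5, 5), 100.0)  # nothing is high-Al
        xrf = make_map(p=p, al=al, shape=(5, 5))
        phases = PhaseLabels(np.full((5, 5), MIXED))
        out = elemental_classes(
            xrf,
            phases,
            DistancePlane(np.full((5, 5), 20.0)),
            thresholds={"P": 9000.0, "Al": 5000.0, "S": 1e9, "Si": 1e9},
            pairs=(("P", "Al"),),
        )
        assert out["classes"]["highP_highAl"]["empty"] is True
        assert out["classes"]["highP_highAl"]["count"] == 0


class TestRegistration:
    def test_identity_transform_samples_first_slice(self):
        vol = np.arange(5 * 6 * 3, dtype=float).reshape(5, 6, 3)
        xrf = make_map(shape=(5, 6), pixel=1.0)
        plane = register_plane(xrf, vol, voxel_size=1.0)
        np.testing.assert_array_equal(plane.distances_um, vol[:, :, 0])

    def test_translation_by_one_voxel(self):
        vol = np.arange(5 * 6 * 3, dtype=float).reshape(5, 6, 3)
        affine = np.hstack([np.eye(3), np.array([[0.0], [0.0], [1.0]])])
        xrf = make_map(shape=(5, 6), pixel=1.0)
        xrf.affine = affine
        plane = register_plane(xrf, vol, voxel_size=1.0)
        np.testing.assert_array_equal(plane.distances_um, vol[:, :, 1])

    def test_quarter_turn_rotation_samples_expected_lattice(self):
        rng = np.random.default_rng(2)
        vol = rng.random((8, 8, 3))
        # rotate the plane 90 degrees about the volume z axis, shifted to
        # stay in bounds: pixel (r, c) -> voxel (7 - c, r, 1)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([7.0, 0.0, 1.0])
        xrf = make_map(shape=(8, 8), pixel=1.0)
        xrf.affine = np.hstack([R, shift[:, None]])
        plane = register_plane(xrf, vol, voxel_size=1.0)
        expected = np.empty((8, 8))
        for r in range(8):
            for c in range(8):
                expected[r, c] = vol[7 - c, r, 1]
        np.testing.assert_array_equal(plane.distances_um, expected)

    def test_out_of_bounds_plane_reported(self):
        vol = np.zeros((4, 4, 4))
        xrf = make_map(shape=(10, 10), pixel=1.0)
        with pytest.raises(ValueError, match="outside the volume"):
            register_plane(xrf, vol, voxel_size=1.0)
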