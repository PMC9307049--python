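"""XANES preprocessing, linear-combination fitting, speciation trends."""

import numpy as np
import pytest

from mycouptake.synthetic import gen_xanes, gen_xanes_library
from mycouptake.xanes import (
    DEFAULT_S_GROUPS,
    Spectrum,
    lcf_fit,
    preprocess,
    speciation_vs_distance,
)


@pytest.fixture(scope="module")
def s_library():
    return gen_xanes_library("S-K")


class TestPreprocess:
    def test_normalised_spectrum_passes_through(self):
        # zero pre-edge, unit post-edge: nothing to subtract or rescale
        e = np.linspace(0.0, 10.0, 101)
        y = np.clip((e - 4.0) / 2.0, 0.0, 1.0)
        out = preprocess(Spectrum(e, y, edge="S-K"), e)
        np.testing.assert_allclose(out.intensities, y, atol=1e-12)

    def test_preprocess_is_idempotent(self, s_library):
        spec = s_library["thiol"]
        once = preprocess(spec, spec.energies)
        twice = preprocess(once, spec.energies)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_scale_invariance(self, s_library):
        spec = s_library["sulfate"]
        scaled = Spectrum(spec.energies, 5.0 * spec.intensities, edge=spec.edge)
        a = preprocess(spec, spec.energies)
        b = preprocess(scaled, spec.energies)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)

    def test_piecewise_linear_interpolation_is_exact(self):
        # flat zero pre-edge, linear rise, flat unit post-edge: linear
        # interpolation reproduces the curve exactly at any grid point
        e = np.linspace(0.0, 10.0, 101)
        y = np.clip((e - 4.0) / 2.0, 0.0, 1.0)
        spec = Spectrum(e, y, edge="S-K")
        grid = np.linspace(0.5, 9.5, 61)
        out = preprocess(spec, grid)
        expected = np.clip((grid - 4.0) / 2.0, 0.0, 1.0)
        np.testing.assert_allclose(out.intensities, expected, atol=1e-12)

    def test_grid_outside_span_rejected(self, s_library):
        spec = s_library["thiol"]
        with pytest.raises(ValueError, match="outside"):
            preprocess(spec, spec.energies + 100.0)

    def test_spectrum_validation(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(5.0), np.arange(5.0))  # too few points
        e = np.arange(30.0)
        e[10] = e[9]  # non-increasing
        with pytest.raises(ValueError):
            Spectrum(e, np.zeros(30))


class TestLCF:
    def test_pure_standard_recovered_exactly(self, s_library):
        spec, _, _ = gen_xanes({"thiol": 1.0}, snr=np.inf, library=s_library)
        res = lcf_fit(spec, s_library)
        assert res.weights["thiol"] == pytest.approx(1.0, abs=1e-10)
        assert res.weights["sulfonate"] == pytest.approx(0.0, abs=1e-10)
        assert res.rss == pytest.approx(0.0, abs=1e-18)

    def test_weights_sum_to_one_and_are_nonnegative(self, s_library):
        spec, _, _ = gen_xanes(
            {"thiol": 0.3, "sulfonate": 0.3, "sulfate": 0.4},
            snr=20,
            library=s_library,
            seed=4,
        )
        res = lcf_fit(spec, s_library)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(w >= 0 for w in res.weights.values())

    def test_two_component_mixture_recovery(self, s_library):
        errs = []
        for seed in range(20):
            spec, _, _ = gen_xanes(
                {"thiol": 0.6, "sulfate": 0.4}, snr=50, library=s_library, seed=seed
            )
            res = lcf_fit(spec, s_library)
            errs.append(
                abs(res.weights["thiol"] - 0.6) + abs(res.weights["sulfate"] - 0.4)
            )
        assert np.mean(errs) / 2 <= 0.02

    def test_idempotent_on_own_fit(self, s_library):
        spec, _, _ = gen_xanes(
            {"thiol": 0.5, "sulfonate": 0.5}, snr=30, library=s_library, seed=1
        )
        res = lcf_fit(spec, s_library)
        names = list(s_library)
        fitted = sum(
            res.weights[nm] * s_library[nm].intensities for nm in names
        )
        refit = lcf_fit(Spectrum(spec.energies, fitted, edge="S-K"), s_library)
        for nm in names:
            assert refit.weights[nm] == pytest.approx(res.weights[nm], abs=1e-10)

    def test_recovery_improves_with_snr(self, s_library):
        mean_err = []
        for snr in (5.0, 25.0, 125.0):
            errs = []
            for seed in range(15):
                spec, _, _ = gen_xanes(
                    {"thiol": 0.6, "sulfate": 0.4}, snr=snr, library=s_library, seed=seed
                )
                res = lcf_fit(spec, s_library)
                errs.append(abs(res.weights["thiol"] - 0.6))
            mean_err.append(np.mean(errs))
        assert mean_err[0] > mean_err[1] > mean_err[2]

    def test_rank_deficient_library_warns(self, s_library):
        dup = dict(s_library)
        thiol = s_library["thiol"]
        dup["thiol_copy"] = Spectrum(
            thiol.energies, thiol.intensities.copy(), edge="S-K", name="thiol_copy"
        )
        spec, _, _ = gen_xanes({"sulfate": 1.0}, snr=100, library=s_library, seed=0)
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = lcf_fit(spec, dup)
        assert res.rank_warning

    def test_mismatched_edges_rejected(self, s_library):
        p_lib = gen_xanes_library("P-K")
        spec, _, _ = gen_xanes({"thiol": 1.0}, snr=np.inf, library=s_library)
        with pytest.raises(ValueError, match="edge"):
            lcf_fit(spec, p_lib)

    def test_fewer_than_two_standards_rejected(self, s_library):
        spec, _, _ = gen_xanes({"thiol": 1.0}, snr=np.inf, library=s_library)
        with pytest.raises(ValueError):
            lcf_fit(spec, {"thiol": s_library["thiol"]})


class TestSpeciationTrend:
    def _spectra(self, s_library, distances, ox_fracs, snr=200.0):
        out = []
        for i, (d, ox) in enumerate(zip(distances, ox_fracs)):
            spec, _, _ = gen_xanes(
                {"thiol": 1 - ox, "sulfonate": 0.5 * ox, "sulfate": 0.5 * ox},
                snr=snr,
                library=s_library,
                distance_um=d,
                seed=100 + i,
            )
            out.append(spec)
        return out

    def test_single_bin_equals_plain_mean(self, s_library):
        spectra = self._spectra(s_library, [10, 20, 30], [0.2, 0.4, 0.6], snr=np.inf)
        trend = speciation_vs_distance(spectra, s_library, [0.0, 100.0])
        ox = trend[trend.group == "oxidized"].iloc[0]
        assert ox["mean_fraction"] == pytest.approx(0.4, abs=1e-6)
        assert ox["n"] == 3

    def test_planted_gradient_recovered_monotone(self, s_library):
        d = [25, 75, 150, 300]
        spectra = self._spectra(s_library, d, [0.8, 0.6, 0.4, 0.2])
        trend = speciation_vs_distance(
            spectra, s_library, [0.0, 50.0, 100.0, 200.0, 400.0]
        )
        ox = trend[trend.group == "oxidized"].sort_values("bin_centre_um")
        vals = ox["mean_fraction"].to_numpy()
        assert np.all(np.diff(vals) < 0)

    def test_group_fractions_sum_to_one_per_bin(self, s_library):
        spectra = self._spectra(s_library, [30, 60], [0.3, 0.7])
        trend = speciation_vs_distance(spectra, s_library, [0.0, 50.0, 100.0])
        for _, bin_grp in trend.groupby("bin_lo_um"):
            total = bin_grp["mean_fraction"].sum()
            if bin_grp["n"].iloc[0] > 0:
                assert total == pytest.approx(1.0, abs=1e-6)

    def test_missing_annotation_is_an_error(self, s_library):
        spec, _, _ = gen_xanes({"thiol": 1.0}, snr=np.inf, library=s_library)
        with pytest.raises(ValueError, match="distance"):
            speciation_vs_distance([spec], s_library, [0.0, 100.0])

    def test_default_grouping_covers_standards(self, s_library):
        assert set(DEFAULT_S_GROUPS) == set(s_library)
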