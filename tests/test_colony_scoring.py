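"""Colony detection, growth estimation and necrosis line-scan scoring."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import organostack.colony_scoring as cs
from organostack.synthetic_data import (
    evaluate_classifier_benchmark,
    gen_classifier_benchmark,
    gen_colony_field,
    gen_growth_cohort,
)


class TestDetectFoci:
    def test_blank_image_has_no_foci(self):
        img = cs.FluorescenceImage(np.zeros((128, 128)), pixel_size=1.6)
        assert cs.detect_foci(img) == []

    def test_textured_background_without_colonies(self):
        img, _ = gen_colony_field(field_um=(400, 400), n_colonies=0, seed=2)
        assert cs.detect_foci(img) == []

    def test_forty_nine_single_cells_all_found(self):
        # a day-1 field: 49 spots, the per-field average seen after seeding
        img, truth = gen_colony_field(
            field_um=(1049, 1049), pixel_size=1.6, n_colonies=49,
            radius_um=10.0, min_separation_factor=4.0, seed=3)
        recs = cs.detect_foci(img)
        assert len(recs) == 49
        # every detection lies on a true colony
        for rec in recs:
            x = rec.centroid[1] * 1.6
            y = rec.centroid[0] * 1.6
            assert np.hypot(truth.x_um - x, truth.y_um - y).min() < 10.0

    def test_exact_count_for_separated_clean_colonies(self):
        img, truth = gen_colony_field(
            field_um=(1000, 1000), n_colonies=15, radius_um=(15, 30),
            halo_sigma_um=0.0, noise_model=None, min_separation_factor=2.5,
            seed=4)
        assert len(cs.detect_foci(img)) == len(truth)

    def test_two_close_foci_merge_into_one(self):
        cols = [dict(x_um=200, y_um=200, radius_um=20),
                dict(x_um=228, y_um=200, radius_um=20)]  # 1.4 radii apart
        img, _ = gen_colony_field(field_um=(400, 400), colonies=cols,
                                  halo_sigma_um=0.0, noise_model=None, seed=5)
        assert len(cs.detect_foci(img)) == 1

    def test_recovered_volumes_within_ten_percent(self):
        img, truth = gen_colony_field(
            field_um=(1200, 1200), n_colonies=12, radius_um=(20, 45),
            halo_sigma_um=0.0, noise_model=None, background_level=0.0,
            seed=5)
        recs = cs.detect_foci(img)
        assert len(recs) == len(truth)
        got = np.sort([r.sphere_volume for r in recs])
        want = np.sort(truth.sphere_volume_um3.to_numpy())
        np.testing.assert_allclose(got, want, rtol=0.10)


class TestSphereVolume:
    def test_closed_form(self):
        area = math.pi * 10.0 ** 2
        assert cs.sphere_volume_from_area(area) == pytest.approx(4188.79, rel=1e-5)

    def test_quadrupling_area_octuples_volume(self):
        v1 = cs.sphere_volume_from_area(50.0)
        v8 = cs.sphere_volume_from_area(200.0)
        assert v8 == pytest.approx(8 * v1)

    @given(r=st.floats(0.5, 500.0))
    def test_roundtrip_through_projected_area(self, r):
        area = math.pi * r ** 2
        v = cs.sphere_volume_from_area(area)
        assert (3.0 * v / (4.0 * math.pi)) ** (1 / 3) == pytest.approx(r)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            cs.sphere_volume_from_area(0.0)


class TestDoublingTime:
    def test_512_fold_in_nine_days_is_24h(self):
        assert cs.doubling_time([1.0], [512.0], 216.0) == pytest.approx(24.0)

    def test_no_growth_is_infinite(self):
        assert math.isinf(cs.doubling_time([2.0, 2.0], [2.0, 2.0], 24.0))

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            cs.doubling_time([1.0, -1.0], [2.0], 24.0)

    def test_recovered_from_noisy_synthetic_cohort(self):
        table = gen_growth_cohort(n_colonies=20, doubling=24.0,
                                  days=(1, 10), lognormal_cv=0.3, seed=11)
        v0 = table[table.day == 1].volume_um3
        v1 = table[table.day == 10].volume_um3
        tau = cs.doubling_time(v0, v1, 216.0)
        assert 20.0 <= tau <= 28.0


class TestAnalyticProfile:
    def test_full_sphere_center_is_peak(self):
        scan = cs.analytic_sphere_profile(20.0, 0.0)
        center = scan.intensities[np.argmin(np.abs(scan.positions - 50.0))]
        assert center == pytest.approx(100.0)

    def test_quarter_volume_core_gives_37_percent(self):
        scan = cs.analytic_sphere_profile(20.0, 0.25, n_points=2001)
        center = scan.intensities[np.argmin(np.abs(scan.positions - 50.0))]
        assert center == pytest.approx(100.0 * (1 - 0.25 ** (1 / 3)), abs=1e-6)
        assert round(center) == 37

    def test_fully_dark_core_zero_center(self):
        scan = cs.analytic_sphere_profile(20.0, 1.0, n_points=2001)
        center = scan.intensities[np.argmin(np.abs(scan.positions - 50.0))]
        assert center == pytest.approx(0.0, abs=1e-9)


class TestClassifyNecrosis:
    @staticmethod
    def flat100():
        return cs.LineScan(np.linspace(0, 100, 101), np.full(101, 100.0))

    @staticmethod
    def dip(at=50.0, to=20.0):
        pos = np.linspace(0, 100, 101)
        inten = np.full(101, 100.0)
        inten[np.abs(pos - at) < 3] = to
        return cs.LineScan(pos, inten)

    def test_two_flat_profiles_no_valley(self):
        assert cs.classify_necrosis(self.flat100(), self.flat100()) \
            == cs.NecrosisClass.NO_VALLEY

    def test_single_dip_marks_fiber(self):
        assert cs.classify_necrosis(self.dip(), self.flat100()) \
            == cs.NecrosisClass.SINGLE_VALLEY_FIBER

    def test_dip_outside_middle_two_thirds_ignored(self):
        assert cs.classify_necrosis(self.dip(at=8.0), self.flat100()) \
            == cs.NecrosisClass.NO_VALLEY

    def test_both_core_profiles_flag_necrosis(self):
        # a 30%-volume core gives center 1 - 0.3**(1/3) = 33.1% < 37%
        px = cs.analytic_sphere_profile(20.0, 0.30, axis="longest")
        py = cs.analytic_sphere_profile(20.0, 0.30, axis="orthogonal")
        assert cs.classify_necrosis(px, py, reference="sphere") \
            == cs.NecrosisClass.POSSIBLY_NECROTIC

    def test_decision_boundary_at_quarter_volume(self):
        # noise-free analytic profiles referenced to the full-sphere peak:
        # flagged exactly when 1 - f**(1/3) < 0.37, i.e. f > 0.25
        for f in np.linspace(0.0, 1.0, 41):
            px = cs.analytic_sphere_profile(25.0, f, n_points=1001)
            py = cs.analytic_sphere_profile(25.0, f, n_points=1001)
            got = cs.classify_necrosis(px, py, reference="sphere")
            expect_flag = (1 - f ** (1 / 3)) < 0.37
            assert (got == cs.NecrosisClass.POSSIBLY_NECROTIC) == expect_flag, f

    def test_unnormalized_profile_warns_and_normalizes(self):
        pos = np.linspace(0, 100, 101)
        raw = cs.LineScan(pos, np.full(101, 55.0))
        with pytest.warns(UserWarning, match="normaliz"):
            got = cs.classify_necrosis(raw, raw, reference="self")
        assert got == cs.NecrosisClass.NO_VALLEY


class TestExtractProfiles:
    def _single_colony(self, fiber=False, core=0.0):
        cols = [dict(x_um=200, y_um=200, radius_um=40, core_fraction=core,
                     fiber=fiber, fiber_angle=0.0, fiber_radius_um=12.0,
                     fiber_attenuation=0.7, fiber_offset_um=0.0)]
        img, _ = gen_colony_field(field_um=(400, 400), colonies=cols,
                                  noise_model=None, seed=6)
        recs = cs.detect_foci(img)
        assert len(recs) == 1
        return img, recs[0]

    def test_circular_colony_profiles_agree(self):
        img, rec = self._single_colony()
        px, py = cs.extract_profiles(img, rec)
        nx = np.interp(np.linspace(0, 100, 50), px.positions, px.intensities)
        ny = np.interp(np.linspace(0, 100, 50), py.positions, py.intensities)
        assert np.max(np.abs(nx - ny)) < 2.0  # a.u., rotational symmetry

    def test_profiles_peak_exactly_100(self):
        img, rec = self._single_colony(core=0.3)
        for scan in cs.extract_profiles(img, rec):
            assert scan.intensities.max() == pytest.approx(100.0)

    def test_fiber_valley_in_exactly_one_profile(self):
        img, rec = self._single_colony(fiber=True)
        px, py = cs.extract_profiles(img, rec)
        assert cs.classify_necrosis(px, py, reference="sphere") \
            == cs.NecrosisClass.SINGLE_VALLEY_FIBER


class TestClassifierBenchmark:
    def test_sensitivity_and_specificity_at_least_090(self):
        img, truth = gen_classifier_benchmark(seed=0)
        res = evaluate_classifier_benchmark(img, truth)
        assert res["sensitivity"] >= 0.9
        assert res["specificity"] >= 0.9


class TestSeedingArithmetic:
    def test_mesh_chamber_volume_holds_about_five_cells(self):
        n = cs.expected_cell_count(1e5, dims=(400, 400, 340))
        assert n == pytest.approx(5.44, abs=0.01)
        assert round(n) == 5

    def test_microliter_scale(self):
        assert cs.expected_cell_count(1e5, volume_ul=1.1) == pytest.approx(110.0)

    def test_zero_density(self):
        assert cs.expected_cell_count(0.0, volume_ul=5.0) == 0.0

    @pytest.mark.parametrize("n_col,n_seed,expected", [
        (0, 5, 0.0),
        (2, 5, 40.0),
        (7, 7, 100.0),
    ])
    def test_cloning_efficiency(self, n_col, n_seed, expected):
        assert cs.cloning_efficiency(n_col, n_seed) == pytest.approx(expected)

    def test_cloning_efficiency_rejects_zero_seeded(self):
        with pytest.raises(ValueError):
            cs.cloning_efficiency(1, 0)
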