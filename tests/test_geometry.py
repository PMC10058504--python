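import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beadcolony as bc


class TestDescriptors:
    @pytest.mark.parametrize("area, perimeter, expected", [
        (np.pi, 2 * np.pi, 1.0),            # unit circle
        (1.0, 4.0, np.pi / 4),              # unit square
    ])
    def test_circularity_analytic(self, area, perimeter, expected):
        assert bc.circularity(area, perimeter) == pytest.approx(expected, rel=1e-12)

    def test_circularity_sliver_tends_to_zero(self):
        # a degenerate sliver at fixed perimeter has vanishing circularity
        assert bc.circularity(1e-9, 4.0) < 1e-8

    def test_circularity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bc.circularity(0.0, 1.0)
        with pytest.raises(ValueError):
            bc.circularity(1.0, -2.0)

    def test_circularity_above_one_warns(self):
        with pytest.warns(UserWarning):
            bc.circularity(2 * np.pi, 2 * np.pi)

    @pytest.mark.parametrize("major, minor, expected", [
        (2.0, 2.0, 1.0),
        (3.9, 3.0, 1.3),   # the typical monoculture aspect ratio
    ])
    def test_aspect_ratio(self, major, minor, expected):
        assert bc.aspect_ratio(major, minor) == pytest.approx(expected)

    def test_aspect_ratio_alternate_form_on_exact_ellipse(self):
        # ellipse with full axes 4 and 2 has area 2π and AR 2 either way
        area = np.pi * 2.0 * 1.0
        assert bc.aspect_ratio(4.0, 2.0) == pytest.approx(2.0)
        assert bc.aspect_ratio_from_area(area, 2.0) == pytest.approx(2.0)

    def test_aspect_ratio_rejects_zero_minor(self):
        with pytest.raises(ValueError):
            bc.aspect_ratio(1.0, 0.0)

    @given(scale=st.floats(0.01, 100.0), major=st.floats(1.0, 50.0),
           ar=st.floats(1.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, major, ar):
        minor = major / ar
        area = np.pi * major * minor / 4.0
        perim = bc.ramanujan_perimeter(major, minor)
        c0 = bc.circularity(area, perim)
        c1 = bc.circularity(area * scale**2, perim * scale)
        assert c1 == pytest.approx(c0, rel=1e-9)
        assert bc.aspect_ratio(major * scale, minor * scale) == \
            pytest.approx(bc.aspect_ratio(major, minor), rel=1e-12)


class TestVolume:
    def test_sphere_limit(self):
        r = 3.0
        assert bc.colony_volume(2 * r, 2 * r) == pytest.approx(4 / 3 * np.pi * r**3)

    def test_direct_evaluation(self):
        assert bc.colony_volume(4.0, 2.0) == pytest.approx(8 * np.pi / 3)

    @given(major=st.floats(0.5, 200.0), ar=st.floats(1.0, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_axes_form_equals_area_form(self, major, ar):
        # the (area, AR) re-expression is an algebraic identity for ellipses
        minor = major / ar
        area = np.pi * major * minor / 4.0
        v_axes = bc.colony_volume(major, minor)
        v_area = bc.colony_volume_from_area(area, ar)
        assert abs(v_axes - v_area) / v_axes < 1e-9


class TestBeadScaleEstimators:
    @pytest.mark.parametrize("ratio, expected", [
        (1024.0, 10.0), (1.0, 0.0),
    ])
    def test_generations(self, ratio, expected):
        assert bc.generations(ratio * bc.V_ECOLI_UM3) == pytest.approx(expected)

    def test_generations_million_cells(self):
        # ~10^6 cells from one founder: 19.93 doublings, 19 completed
        g = bc.generations(1e6 * bc.V_ECOLI_UM3)
        assert g == pytest.approx(19.93, abs=0.01)
        assert bc.generations_floor(1e6 * bc.V_ECOLI_UM3) == 19

    def test_generations_monotone(self):
        v = np.array([10.0, 100.0, 1e4, 1e6])
        assert np.all(np.diff(bc.generations(v)) > 0)

    def test_generations_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bc.generations(0.0)

    def test_occupancy(self):
        assert bc.occupancy(0.0) == 0.0
        assert bc.occupancy(6e5, n=2, v_bead_um3=2.4e8) == pytest.approx(0.25)

    def test_occupancy_final_population_regime(self):
        # 1e5–1e6 cells of 1.3 μm³ in a 240 nL bead: combined occupancy
        # 0.054%–0.54% (the sub-percent regime of the study)
        for cells, expected in [(1e5, 0.0542), (1e6, 0.5417)]:
            per_strain_v = cells * bc.V_ECOLI_UM3 / 2
            combined = 2 * bc.occupancy(per_strain_v, n=2, v_bead_um3=2.4e8)
            assert combined == pytest.approx(expected, abs=1e-3)

    def test_occupancy_warns_when_colony_exceeds_bead(self):
        with pytest.warns(UserWarning):
            o = bc.occupancy(3e8, n=2, v_bead_um3=2.4e8)
        assert o > 100.0

    def test_population_estimate(self):
        assert bc.population_estimate(0.0, 0.0).total == 0.0
        est = bc.population_estimate(6.5e5, 6.5e5, n=2, v_cell=1.3)
        assert est.total == pytest.approx(1e6)
        assert est.n_b == pytest.approx(5e5)

    def test_population_linear_in_volume(self):
        a = bc.population_estimate(1e5, 2e5).total
        b = bc.population_estimate(2e5, 4e5).total
        assert b == pytest.approx(2 * a)

    def test_population_rejects_bad_cell_volume(self):
        with pytest.raises(ValueError):
            bc.population_estimate(1.0, 1.0, v_cell=0.0)


class TestMaskMeasurement:
    @pytest.mark.parametrize("major, minor, orientation", [
        (60.0, 40.0, 0.0), (100.0, 20.0, 0.7), (80.0, 62.0, 1.3),
    ])
    def test_measured_ar_matches_analytic(self, major, minor, orientation):
        mask = bc.rasterize_ellipse(major, minor, orientation)
        shape = bc.measure_mask(mask)
        measured = bc.aspect_ratio(shape.major_axis, shape.minor_axis)
        assert measured == pytest.approx(major / minor, rel=0.02)

    def test_measured_area_close_to_ellipse_area(self):
        mask = bc.rasterize_ellipse(80.0, 50.0)
        shape = bc.measure_mask(mask)
        assert shape.area == pytest.approx(np.pi * 40.0 * 25.0, rel=0.03)

    def test_measure_mask_requires_single_region(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        with pytest.raises(ValueError):
            bc.measure_mask(mask)


def test_annotate_shapes_adds_descriptor_columns(small_table):
    out = bc.annotate_shapes(small_table)
    for col in ("circularity", "aspect_ratio", "volume_um3", "generations",
                "occupancy_pct"):
        assert col in out.columns
    assert np.all(out["aspect_ratio"] >= 1.0)
    assert np.all((out["circularity"] > 0) & (out["circularity"] <= 1.0 + 1e-9))
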