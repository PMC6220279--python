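"""Stereological probes and estimators: mechanics, identities, unbiasedness."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from stereomorph.phantom import (RegionSpec, make_phantom, populate_cells,
                                 section_phantom)
from stereomorph.stereology import (DisectorCount, SamplingDesign,
                                    apply_counting_frame, cavalieri_volume,
                                    count_ce, density_count,
                                    fractionator_count, group_precision,
                                    gundersen_jensen_ce, layer_band_volumes,
                                    layerwise_counts, nucleator_area,
                                    optical_disector, place_disector_stacks)


def exhaustive_design(T: float = 40.0) -> SamplingDesign:
    """All sampling fractions equal to 1."""
    return SamplingDesign(section_period=1, section_thickness_um=T,
                          step_x_um=100.0, step_y_um=100.0,
                          frame_width_um=100.0, frame_height_um=100.0,
                          disector_top_um=0.0, disector_bottom_um=T)


class TestSamplingDesign:
    def test_study_design_fractions(self):
        d = SamplingDesign()
        assert d.ssf == pytest.approx(1 / 6)
        assert d.frame_area_um2 == pytest.approx(2000.0)
        assert d.asf == pytest.approx(2000.0 / (400.0 * 400.0))
        assert d.hsf == pytest.approx(10.0 / 40.0)

    def test_inverted_disector_window_rejected(self):
        with pytest.raises(ValueError, match="inverted|window"):
            SamplingDesign(disector_top_um=15.0, disector_bottom_um=5.0)

    def test_frame_must_fit_step_cell(self):
        with pytest.raises(ValueError, match="frame"):
            SamplingDesign(frame_width_um=500.0)


class TestNucleator:
    def test_circle_any_rays_gives_pi_r_squared(self):
        r = 700.0
        circle = lambda x, y: (x - 1000) ** 2 + (y - 1000) ** 2 <= r ** 2
        for n_rays in (2, 4, 7):
            a = nucleator_area(circle, (1000.0, 1000.0), n_rays,
                               phase=0.3, r_max=2000.0)
            assert a == pytest.approx(np.pi * r ** 2, rel=1e-6)

    def test_ellipse_unbiased_over_rotation_phases(self):
        a_ax, b_ax = 800.0, 400.0
        ell = lambda x, y: ((x - 1000) / a_ax) ** 2 + ((y - 1000) / b_ax) ** 2 <= 1
        rng = np.random.default_rng(5)
        ests = [nucleator_area(ell, (1000.0, 1000.0), 4,
                               phase=float(rng.random() * np.pi / 2),
                               r_max=2000.0)
                for _ in range(1000)]
        assert np.mean(ests) == pytest.approx(np.pi * a_ax * b_ax, rel=0.01)

    def test_dense_rays_recover_star_polygon_area(self):
        # star-shaped (about its centroid) polygon; oracle: shapely area
        angles = np.linspace(0, 2 * np.pi, 9, endpoint=False)
        radii = np.array([500, 300, 550, 280, 620, 350, 480, 320, 560], float)
        verts = [(1000 + r * np.cos(t), 1000 + r * np.sin(t))
                 for r, t in zip(radii, angles)]
        poly = Polygon(verts)
        ind = lambda x, y: poly.covers(Point(x, y))
        est = nucleator_area(ind, (1000.0, 1000.0), 2048, phase=0.0,
                             r_max=1500.0)
        assert est == pytest.approx(poly.area, rel=0.005)

    def test_seed_outside_profile_rejected(self):
        circle = lambda x, y: x ** 2 + y ** 2 <= 1
        with pytest.raises(ValueError, match="seed"):
            nucleator_area(circle, (5.0, 5.0), 4, phase=0.0, r_max=10.0)


class TestCountingFrame:
    def test_exclusion_and_inclusion_edges(self):
        pts = np.array([[0.0, 5.0],    # left edge: excluded
                        [5.0, 0.0],    # bottom edge: excluded
                        [5.0, 10.0],   # top edge, x inside: included
                        [10.0, 5.0],   # right edge, y inside: included
                        [5.0, 5.0]])   # interior: included
        acc = apply_counting_frame(pts, (0.0, 0.0), 10.0, 10.0)
        assert acc.tolist() == [False, False, True, True, True]

    def test_tiling_counts_every_point_exactly_once(self, rng):
        pts = rng.random((500, 2)) * 1000.0
        w, h = 130.0, 90.0
        total = np.zeros(len(pts), dtype=int)
        for ix in range(-1, 9):
            for iy in range(-1, 13):
                total += apply_counting_frame(pts, (ix * w, iy * h), w, h)
        assert (total == 1).all()


class TestOpticalDisector:
    def _section(self, cells):
        from stereomorph.phantom import Section
        return Section(0, 0.0, 40.0, {}, (0, 1), cells, (50.0, 50.0, 40.0), 2)

    def test_study_window_height_and_hsf(self):
        d = SamplingDesign(disector_top_um=5.0, disector_bottom_um=15.0)
        assert d.disector_height_um == pytest.approx(10.0)
        assert d.hsf == pytest.approx(10.0 / 40.0)

    def test_empty_slab_counts_zero(self):
        empty = pd.DataFrame(columns=["x_um", "y_um", "z_um", "class",
                                      "pv", "vva", "layer", "region"])
        dc = optical_disector(empty, self._section(empty), (0, 0), 50, 40, (5, 15))
        assert dc.q == 0 and dc.v_dis_um3 == pytest.approx(50 * 40 * 10)

    def test_full_window_full_frame_counts_all(self, rng):
        n = 200
        cells = pd.DataFrame({"x_um": rng.random(n) * 99 + 0.5,
                              "y_um": rng.random(n) * 99 + 0.5,
                              "z_um": rng.random(n) * 40.0})
        dc = optical_disector(cells, self._section(cells), (0, 0), 100, 100, (0, 40))
        assert dc.q == n

    def test_inverted_window_rejected(self):
        cells = pd.DataFrame({"x_um": [1.0], "y_um": [1.0], "z_um": [1.0]})
        with pytest.raises(ValueError, match="inverted"):
            optical_disector(cells, self._section(cells), (0, 0), 50, 40, (15, 5))


class TestFractionator:
    def test_exhaustive_identity_counts_everything(self, cpu_phantom, rng):
        vol, _, cells = cpu_phantom
        series = section_phantom(vol, cells, 40.0, rng=rng)
        est = fractionator_count(series, exhaustive_design(), rng, cell_class=None)
        assert est.estimate == len(cells)

    def test_class_filter_counts_only_neurons(self, cpu_phantom, rng):
        vol, _, cells = cpu_phantom
        series = section_phantom(vol, cells, 40.0, rng=rng)
        est = fractionator_count(series, exhaustive_design(), rng)
        assert est.estimate == (cells["class"] == "neuron").sum()

    def test_doubling_step_leaves_expectation_unchanged(self, cpu_phantom):
        vol, _, cells = cpu_phantom
        base = SamplingDesign(frame_width_um=100.0, frame_height_um=100.0)
        wide = SamplingDesign(step_x_um=800.0, frame_width_um=100.0,
                              frame_height_um=100.0)
        assert wide.asf == pytest.approx(base.asf / 2)
        means = {}
        for name, design in (("base", base), ("wide", wide)):
            ests = []
            for s in range(120):
                r = np.random.default_rng(1000 + s)
                series = section_phantom(vol, cells, 40.0, rng=r,
                                         tally_voxels=False)
                ests.append(fractionator_count(series, design, r).estimate)
            means[name] = np.mean(ests)
        truth = (cells["class"] == "neuron").sum()
        assert means["base"] == pytest.approx(truth, rel=0.03)
        assert means["wide"] == pytest.approx(truth, rel=0.04)

    def test_scale_equivariance(self, rng):
        # scaling all µm coordinates by s leaves counts unchanged and
        # multiplies volume estimates by s³
        s = 2.0
        spec1 = RegionSpec("r", 1, (2000,) * 3, (900.0,) * 3)
        spec2 = RegionSpec("r", 1, (2000 * s,) * 3, (900.0 * s,) * 3)
        vol1, _ = make_phantom([spec1], (40, 40, 50), (100.0, 100.0, 80.0))
        vol2, _ = make_phantom([spec2], (40, 40, 50),
                               (100.0 * s, 100.0 * s, 80.0 * s))
        cells1 = populate_cells(vol1, "r", 3000, np.random.default_rng(3))
        cells2 = cells1.copy()
        cells2[["x_um", "y_um", "z_um"]] *= s
        d1 = SamplingDesign(section_period=2, section_thickness_um=80.0,
                            step_x_um=200.0, step_y_um=200.0,
                            frame_width_um=100.0, frame_height_um=100.0,
                            disector_top_um=10.0, disector_bottom_um=50.0)
        d2 = SamplingDesign(section_period=2, section_thickness_um=80.0 * s,
                            step_x_um=200.0 * s, step_y_um=200.0 * s,
                            frame_width_um=100.0 * s, frame_height_um=100.0 * s,
                            disector_top_um=10.0 * s, disector_bottom_um=50.0 * s)
        ser1 = section_phantom(vol1, cells1, 80.0, start_um=7.0)
        ser2 = section_phantom(vol2, cells2, 80.0 * s, start_um=7.0 * s)
        c1 = fractionator_count(ser1, d1, np.random.default_rng(9), cell_class=None)
        c2 = fractionator_count(ser2, d2, np.random.default_rng(9), cell_class=None)
        assert c1.tallies.sum() == c2.tallies.sum()
        v1 = cavalieri_volume(ser1, "r", d1, start=0)
        v2 = cavalieri_volume(ser2, "r", d2, start=0)
        assert v2.estimate == pytest.approx(v1.estimate * s ** 3, rel=1e-12)

    def test_zero_sampling_fraction_rejected(self):
        with pytest.raises(ValueError):
            SamplingDesign(disector_top_um=5.0, disector_bottom_um=5.0)

    def test_fixed_seed_reproduces_estimate(self, cpu_phantom):
        vol, _, cells = cpu_phantom
        outs = []
        for _ in range(2):
            r = np.random.default_rng(42)
            series = section_phantom(vol, cells, 40.0, rng=r, tally_voxels=False)
            outs.append(fractionator_count(series, SamplingDesign(), r).estimate)
        assert outs[0] == outs[1]


class TestCavalieri:
    def test_every_section_pixel_areas_reproduce_voxel_volume(self, cpu_phantom, rng):
        vol, _, _ = cpu_phantom
        series = section_phantom(vol, None, 40.0, rng=rng)
        est = cavalieri_volume(series, "CPu", exhaustive_design(), rng=rng)
        assert est.estimate == pytest.approx(vol.region_volume_mm3("CPu"), rel=1e-12)

    def test_every_6th_section_unbiased_over_starts(self, sphere_phantom):
        vol, truth = sphere_phantom
        design = SamplingDesign()
        ests = []
        for s in range(60):
            r = np.random.default_rng(s)
            series = section_phantom(vol, None, 40.0, rng=r)
            ests.append(cavalieri_volume(series, "ball", design, rng=r).estimate)
        assert np.mean(ests) == pytest.approx(vol.region_volume_mm3("ball"),
                                              rel=0.01)

    def test_nucleator_areas_approximate_pixel_volume(self, sphere_phantom):
        vol, _ = sphere_phantom
        r = np.random.default_rng(3)
        series = section_phantom(vol, None, 40.0, rng=r)
        design = SamplingDesign(nucleator_rays=8)
        est = cavalieri_volume(series, "ball", design, area_method="nucleator",
                               volume=vol, rng=r)
        assert est.estimate == pytest.approx(vol.region_volume_mm3("ball"),
                                             rel=0.10)

    def test_absent_region_warns_and_returns_zero(self, sphere_phantom, rng):
        vol, _ = sphere_phantom
        vol2 = type(vol)(vol.grid, vol.voxel_size,
                         {**vol.label_map, 9: "ghost"}, vol.hierarchy)
        series = section_phantom(vol2, None, 40.0, rng=rng)
        est = cavalieri_volume(series, "ghost", exhaustive_design(), rng=rng)
        assert est.estimate == 0.0 and "ghost" in est.warning


class TestDensityCount:
    def test_uniform_density_recovered(self, sphere_phantom):
        vol, _ = sphere_phantom
        rng = np.random.default_rng(11)
        n = 20000
        cells = populate_cells(vol, "ball", n, rng,
                               class_mixture={"neuron": 1.0})
        series = section_phantom(vol, cells, 40.0, rng=rng)
        design = SamplingDesign(frame_width_um=135.0, frame_height_um=135.0,
                                disector_top_um=5.0, disector_bottom_um=35.0)
        stacks = place_disector_stacks(
            series, vol, "ball", design, rng,
            stacks_per_layer={"all": 2}, layer_bands={"all": (0.0, 1.0)},
            layer_axis=1)
        est = density_count(stacks, vol.region_volume_mm3("ball"))
        assert est.estimate == pytest.approx(n, rel=0.15)

    def test_zero_counts_give_zero_estimate(self):
        stacks = [DisectorCount(0, 0, 0, 0, 1000.0)]
        est = density_count(stacks, 1.0)
        assert est.estimate == 0.0

    def test_site_bookkeeping(self):
        stacks = [DisectorCount(i, 0, i // 14, 1, 500.0, "V")
                  for i in range(56)]  # 14 stacks × 4 sections
        est = density_count(stacks, 2.5)
        assert est.design["n_stacks"] == 56
        assert est.estimate == pytest.approx(56 / (56 * 500.0) * 2.5e9)

    def test_empty_stacks_rejected(self):
        with pytest.raises(ValueError):
            density_count([], 1.0)


class TestLayerwise:
    BANDS = {"I-III": (0.0, 0.45), "V": (0.45, 0.80), "VI": (0.80, 1.0)}

    def test_band_estimates_sum_to_region_estimate(self):
        # equal sampling intensity: disector volume proportional to band volume
        v_ref = {"I-III": 0.45, "V": 0.35, "VI": 0.20}
        stacks = []
        for lay, v in v_ref.items():
            n = int(v * 100)
            stacks += [DisectorCount(i, 0, 0, 2, 1000.0, lay) for i in range(n)]
        per_band = layerwise_counts(stacks, v_ref)
        whole = density_count(stacks, sum(v_ref.values()))
        assert sum(e.estimate for e in per_band.values()) == pytest.approx(
            whole.estimate, rel=1e-12)

    def test_layer_v_deficit_shows_only_in_layer_v(self, sphere_phantom):
        vol, _ = sphere_phantom
        rng = np.random.default_rng(21)
        design = SamplingDesign(frame_width_um=135.0, frame_height_um=135.0,
                                disector_top_um=5.0, disector_bottom_um=35.0)
        band_v = layer_band_volumes(vol, "ball", self.BANDS, layer_axis=1)

        def estimate(profile):
            cells = populate_cells(vol, "ball", 20000, rng,
                                   class_mixture={"neuron": 1.0},
                                   laminar_profile=profile, layer_axis=1,
                                   layer_bands=self.BANDS)
            series = section_phantom(vol, cells, 40.0, rng=rng)
            stacks = place_disector_stacks(
                series, vol, "ball", design, rng,
                stacks_per_layer={"I-III": 3, "V": 3, "VI": 1},
                layer_bands=self.BANDS, layer_axis=1)
            return {k: e.estimate for k, e in
                    layerwise_counts(stacks, band_v).items()}

        healthy = estimate({"I-III": 0.45, "V": 0.40, "VI": 0.15})
        # 70% of layer-V cells removed, other bands unchanged
        lesioned = estimate({"I-III": 0.45 / 0.72, "V": 0.12 / 0.72,
                             "VI": 0.15 / 0.72})
        ratio = {k: lesioned[k] / healthy[k] for k in healthy}
        assert ratio["V"] < 0.6
        assert ratio["I-III"] > 0.75 and ratio["VI"] > 0.75

    def test_unassigned_stack_rejected(self):
        stacks = [DisectorCount(0, 0, 0, 1, 500.0, "")]
        with pytest.raises(ValueError, match="layer"):
            layerwise_counts(stacks, {"V": 1.0})


class TestPrecision:
    def test_constant_sequence_leaves_only_noise_term(self):
        assert gundersen_jensen_ce([5.0] * 10) == pytest.approx(0.0)
        noise = 2.0
        ce = gundersen_jensen_ce([5.0] * 10, noise=noise)
        assert ce == pytest.approx(np.sqrt(noise) / 50.0)

    def test_count_ce_poisson_floor(self):
        q = [4.0] * 25  # ΣQ = 100, constant sequence: SURS term 0
        assert count_ce(q) == pytest.approx(0.1)

    def test_predicted_ce_within_factor_two_of_empirical(self, sphere_phantom):
        vol, _ = sphere_phantom
        design = SamplingDesign()
        ests, ces = [], []
        for s in range(200):
            r = np.random.default_rng(s)
            series = section_phantom(vol, None, 40.0, rng=r)
            e = cavalieri_volume(series, "ball", design, rng=r)
            ests.append(e.estimate)
            ces.append(e.ce)
        emp_cv = np.std(ests) / np.mean(ests)
        pred = np.nanmean(ces)
        assert pred / emp_cv > 0.5 and pred / emp_cv < 2.0

    def test_group_summary_ratio_definition(self):
        from stereomorph.stereology import StereoEstimate
        ests = [StereoEstimate("number", v, 0.05, np.array([]))
                for v in (100.0, 110.0, 95.0, 105.0)]
        g = group_precision(ests)
        assert g.cv == pytest.approx(np.std([100, 110, 95, 105], ddof=1)
                                     / np.mean([100, 110, 95, 105]))
        assert g.ce2_over_cv2 == pytest.approx(0.05 ** 2 / g.cv ** 2)
        assert g.ce2_over_cv2 < 1.0
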