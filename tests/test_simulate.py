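"""Generator contracts: determinism, noise model, radial structure,
ground-truth geometry and the embedded confinement law."""

import math

import numpy as np
import pandas as pd
import pytest

import mitopattern as mp
from mitopattern import simulate as sim
from mitopattern.simulate import GeneratorParams, ParameterError, GeometryError

from conftest import NOISELESS


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"island_radius_um": 0.0},
            {"pixel_size_um": -1.0},
            {"stromal_density": -5.0},
            {"peak_radius": 0.0},
            {"peak_radius": 1.2},
            {"fccp_residual_fraction": 1.5},
            {"orr_center": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises((ParameterError, GeometryError)):
            GeneratorParams(**kwargs)

    def test_too_small_extent_rejected(self):
        with pytest.raises(GeometryError):
            GeneratorParams(extent_factor=1.5)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = GeneratorParams(island_radius_um=300, pixel_size_um=4, seed=7)
        img1, truth1 = mp.generate_micropattern(p)
        img2, truth2 = mp.generate_micropattern(p)
        for ch in img1:
            assert np.array_equal(img1[ch], img2[ch])
        pd.testing.assert_frame_equal(truth1.cells, truth2.cells)

    def test_different_seed_differs(self):
        a, _ = mp.generate_micropattern(GeneratorParams(island_radius_um=300, pixel_size_um=4, seed=1))
        b, _ = mp.generate_micropattern(GeneratorParams(island_radius_um=300, pixel_size_um=4, seed=2))
        assert not np.array_equal(a["TMRM"], b["TMRM"])


class TestNoiseModel:
    def test_noiseless_tmrm_equals_analytic_expectation(self, profile_scale_noiseless):
        img, truth = profile_scale_noiseless
        shape = img.shape
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        cy, cx = truth.center_xy[1], truth.center_xy[0]
        r = np.hypot(yy - cy, xx - cx) / truth.radius_px
        expected = truth.params.tmrm_expectation(r)
        assert np.allclose(img["TMRM"], expected)

    def test_zero_amplitude_noiseless_is_flat_inside_island(self):
        p = GeneratorParams(
            island_radius_um=300, pixel_size_um=4, tmrm_peak_amplitude=0.0, **NOISELESS
        )
        img, truth = mp.generate_micropattern(p)
        shape = img.shape
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        r = np.hypot(yy - truth.center_xy[1], xx - truth.center_xy[0]) / truth.radius_px
        inside = r <= 1.0
        assert np.all(img["TMRM"][inside] == p.tmrm_baseline)

    def test_radial_symmetry_along_four_rays(self):
        # odd image size -> integer pixel center, so rays align exactly
        p = GeneratorParams(island_radius_um=505, pixel_size_um=4, **NOISELESS)
        img, truth = mp.generate_micropattern(p)
        tmrm = img["TMRM"]
        assert img.shape[0] % 2 == 1
        cy = int(truth.center_xy[1])
        cx = int(truth.center_xy[0])
        n = int(truth.radius_px) - 1
        rays = [
            tmrm[cy, cx : cx + n],
            tmrm[cy, cx : cx - n : -1],
            tmrm[cy : cy + n, cx],
            tmrm[cy : cy - n : -1, cx],
        ]
        for ray in rays[1:]:
            assert np.allclose(ray, rays[0], atol=1e-9)


class TestGroundTruthGeometry:
    def test_cancer_cells_inside_island_stroma_outside(self, cell_scale):
        _, truth = cell_scale
        cancer = truth.cells[truth.cells["region"] == "cancer"]
        stroma = truth.cells[truth.cells["region"] == "stroma"]
        assert (cancer["r_norm"] <= 1.0).all()
        assert (stroma["r_norm"] > 1.0).all()

    def test_profile_nonnegative(self, cell_scale):
        _, truth = cell_scale
        assert (truth.f_samples >= 0).all()

    def test_expected_channels_present(self, cell_scale):
        img, _ = cell_scale
        assert set(img.channel_names) == {
            "DAPI", "panCK", "vimentin", "TMRM", "TOM20", "NADPH", "FAD", "YAP"
        }


@pytest.fixture(scope="module")
def flat_noiseless():
    p = GeneratorParams(
        island_radius_um=300, pixel_size_um=4, tmrm_peak_amplitude=0.0,
        tmrm_baseline=100.0, tmrm_stroma=100.0, **NOISELESS
    )
    return mp.generate_micropattern(p)


class TestFccp:

    def test_residual_zero_kills_tmrm(self, flat_noiseless):
        from dataclasses import replace

        img, truth = flat_noiseless
        img0, truth0 = mp.generate_micropattern(
            replace(truth.params, fccp_residual_fraction=0.0)
        )
        fccp_img, _ = mp.apply_fccp(img0, truth0)
        assert np.all(fccp_img["TMRM"] == 0.0)

    def test_residual_one_is_identity(self, flat_noiseless):
        img, truth = flat_noiseless
        from dataclasses import replace

        img1, truth1 = mp.generate_micropattern(
            replace(truth.params, fccp_residual_fraction=1.0)
        )
        fccp_img, _ = mp.apply_fccp(img1, truth1)
        assert np.array_equal(fccp_img["TMRM"], img1["TMRM"])

    def test_residual_scales_flat_profile(self, flat_noiseless):
        from dataclasses import replace

        img, truth = flat_noiseless
        img2, truth2 = mp.generate_micropattern(
            replace(truth.params, fccp_residual_fraction=0.2)
        )
        fccp_img, fccp_truth = mp.apply_fccp(img2, truth2)
        assert np.allclose(fccp_img["TMRM"], 20.0)
        assert np.allclose(fccp_truth.f_samples, 0.2 * truth2.f_samples)

    def test_other_channels_untouched(self, cell_scale):
        img, truth = cell_scale
        fccp_img, _ = mp.apply_fccp(img, truth)
        for ch in img:
            if ch == "TMRM":
                continue
            assert np.array_equal(fccp_img[ch], img[ch])


DENSITIES = [0.0, 221.0, 442.0, 884.0]


@pytest.fixture(scope="module")
def series():
    base = GeneratorParams(island_radius_um=400, pixel_size_um=4, seed=11)
    return sim.generate_density_series(base, DENSITIES)


class TestDensitySeries:
    DENSITIES = DENSITIES

    def test_confinement_law_exact_in_truth(self, series):
        a0 = series[0][1].island_area_mm2
        base = series[0][1].params
        for s, (_, truth) in zip(self.DENSITIES, series):
            assert math.isclose(
                math.log(truth.island_area_mm2 / a0),
                -base.k_prime * s * base.t_days,
                abs_tol=1e-12,
            )

    def test_zero_density_keeps_unconfined_area(self, series):
        base = GeneratorParams(island_radius_um=400, pixel_size_um=4)
        assert math.isclose(
            series[0][1].island_area_mm2, math.pi * 0.4**2, rel_tol=1e-12
        )

    def test_half_area_at_ln2(self):
        # choose k' so k' * s * t = ln 2 at s = 442
        k = math.log(2) / (442.0 * 4.0)
        base = GeneratorParams(island_radius_um=400, pixel_size_um=4, k_prime=k, seed=1)
        members = sim.generate_density_series(base, [0.0, 442.0])
        assert math.isclose(
            members[1][1].island_area_mm2, 0.5 * members[0][1].island_area_mm2,
            rel_tol=1e-12,
        )

    def test_truth_peak_areas_strictly_decreasing(self, series):
        areas = [t.peak_annulus_area() for _, t in series[1:]]  # 221, 442, 884
        assert areas[0] > areas[1] > areas[2]

    def test_edge_density_increases_with_stroma(self, series):
        edge = [t.params.cancer_density_edge for _, t in series]
        assert edge == sorted(edge) and edge[0] < edge[-1]

    def test_negative_density_rejected(self):
        base = GeneratorParams(island_radius_um=300, pixel_size_um=4)
        with pytest.raises(ParameterError):
            sim.generate_density_series(base, [-1.0])


class TestPresets:
    @pytest.mark.parametrize(
        "name,peak",
        [("open_edge", 0.67), ("coculture_25k", 0.85),
         ("coculture_50k", 0.91), ("coculture_100k", 0.92)],
    )
    def test_preset_encodes_peak_radius(self, name, peak):
        params = sim.preset(name)
        grid = np.linspace(0, 1, 2001)
        f = params.tmrm_expectation(grid)
        assert abs(grid[np.argmax(f)] - peak) < 1e-3

    def test_preset_fold_calibration(self):
        params = sim.preset("coculture_50k")
        truth_fold = sim.GroundTruth(
            cells=pd.DataFrame(), center_xy=(0, 0), radius_px=1.0,
            radius_um=params.island_radius_um, params=params,
            radial_grid=np.linspace(0, 1.2, 1201),
            f_samples=params.tmrm_expectation(np.linspace(0, 1.2, 1201)),
        )
        assert math.isclose(truth_fold.expected_fold("TMRM"), 3.1, rel_tol=1e-6)
        assert math.isclose(truth_fold.expected_fold("TOM20"), 1.7, rel_tol=1e-6)

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            sim.preset("nope")
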