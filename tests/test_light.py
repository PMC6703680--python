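"""Canopy radiative transfer: grid layout, Monte Carlo energy accounting,
organ-level R:FR perception and its response to shading."""

import math

import numpy as np
import pytest

from shadegame.architecture import (Leaf, Plant, PlasticityStrategy,
                                    SurfacePatches, leaf_geometry,
                                    stand_patches)
from shadegame.light import (LightSourceSpec, StandLayout, compute_lai,
                             compute_light, daily_par_dose, focal_index,
                             grid_positions, mean_plant_rfr)


def horizontal_lamina(area=0.01, z=0.0, x=0.0, y=0.0,
                      plant_index=0) -> SurfacePatches:
    """Single flat circular-ish lamina patch at height z."""
    b = math.sqrt(area / (2 * math.pi))
    a = 2 * b
    c = np.array([[x, y, z]])
    return SurfacePatches(
        centers=c, normals=np.array([[0.0, 0.0, 1.0]]),
        ua=np.array([[1.0 / a, 0.0, 0.0]]),
        vb=np.array([[0.0, 1.0 / b, 0.0]]),
        areas=np.array([area]), kinds=np.zeros(1, dtype=np.int8),
        plant_idx=np.array([plant_index], dtype=np.int32),
        leaf_idx=np.array([0], dtype=np.int32), sensors=c.copy())


@pytest.fixture
def layout():
    return StandLayout(density=100.0, rows=3, cols=3)


class TestGrid:
    @pytest.mark.parametrize("density,spacing", [
        (100.0, 0.1), (6400.0, 0.0125), (711.0, 711.0 ** -0.5),
    ])
    def test_spacing_is_inverse_root_density(self, density, spacing):
        assert StandLayout(density, 3, 3).spacing == pytest.approx(spacing)

    def test_focal_plant_at_exact_centre(self):
        layout = StandLayout(400.0, 5, 5)
        pos = grid_positions(layout)
        assert pos.shape == (25, 2)
        np.testing.assert_allclose(pos[focal_index(layout)], [0.0, 0.0],
                                   atol=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            StandLayout(0.0, 3, 3)

    def test_too_small_stand_rejected(self):
        with pytest.raises(ValueError):
            StandLayout(100.0, 2, 2)


class TestComputeLight:
    def test_unshaded_lamina_sees_the_source(self, layout, small_source):
        patches = horizontal_lamina(area=0.02, z=0.01)
        sample = compute_light(patches, layout, small_source,
                               np.random.default_rng(0))
        rfr = sample.perceived_rfr[0]
        par = sample.perceived[0, 2]
        assert rfr == pytest.approx(2.3, rel=0.02)
        assert par == pytest.approx(220.0, rel=0.05)

    def test_shaded_lamina_sees_lower_rfr_and_par(self, layout, small_source):
        below = horizontal_lamina(area=0.02, z=0.01)
        above = horizontal_lamina(area=0.05, z=0.05)
        both = SurfacePatches.concat([below, above])
        rng = np.random.default_rng(0)
        shaded = compute_light(both, layout, small_source, rng)
        assert shaded.perceived_rfr[0] < 2.3
        assert shaded.perceived[0, 2] < 220.0
        # the upper lamina sees far-red-enriched reflection from below, so
        # its ratio sits under the source ratio but above the shaded leaf's
        assert shaded.perceived_rfr[0] < shaded.perceived_rfr[1] <= 2.3

    def test_empty_scene_returns_zero_absorption(self, layout, small_source):
        sample = compute_light(SurfacePatches.empty(), layout, small_source,
                               np.random.default_rng(0))
        assert sample.absorbed.size == 0
        assert sample.emitted.sum() == 0.0

    def test_energy_conservation_per_band(self, layout, small_source):
        patches = SurfacePatches.concat([
            horizontal_lamina(area=0.03, z=0.02),
            horizontal_lamina(area=0.03, z=0.05, x=0.02),
            horizontal_lamina(area=0.02, z=0.08, y=-0.03),
        ])
        sample = compute_light(patches, layout, small_source,
                               np.random.default_rng(1))
        np.testing.assert_allclose(sample.energy_closure(), 1.0, rtol=0.01)

    def test_perceived_rfr_never_exceeds_source_ratio(self, layout,
                                                      small_source):
        rng = np.random.default_rng(2)
        parts = [horizontal_lamina(area=0.01,
                                   z=float(0.01 + 0.02 * i),
                                   x=float(rng.uniform(-0.05, 0.05)),
                                   y=float(rng.uniform(-0.05, 0.05)))
                 for i in range(6)]
        sample = compute_light(SurfacePatches.concat(parts), layout,
                               small_source, rng)
        rfr = sample.perceived_rfr
        assert np.nanmax(rfr) <= 2.3 + 1e-9

    def test_added_cover_never_helps_target(self, layout):
        """More opaque area above a fixed organ cannot raise its PAR or its
        R:FR (averaged over repeated light draws)."""
        source = LightSourceSpec(ray_count=900, sensor_up_rays=32,
                                 sensor_down_rays=8)
        target = horizontal_lamina(area=0.02, z=0.01)

        def averages(patches, seed):
            pars, rfrs = [], []
            rng = np.random.default_rng(seed)
            for _ in range(10):
                s = compute_light(patches, layout, source, rng)
                pars.append(s.perceived[0, 2])
                rfrs.append(s.perceived_rfr[0])
            return np.mean(pars), np.mean(rfrs)

        par0, rfr0 = averages(target, 5)
        par1, rfr1 = averages(SurfacePatches.concat(
            [target, horizontal_lamina(area=0.08, z=0.05)]), 5)
        assert par1 <= par0
        assert rfr1 <= rfr0

    def test_tiling_invariance(self, layout, small_source):
        """Translating the stand by one full period changes nothing."""
        patches = SurfacePatches.concat([
            horizontal_lamina(area=0.02, z=0.02, x=0.04),
            horizontal_lamina(area=0.03, z=0.05, x=-0.06, y=0.1),
        ])
        Lx, _ = layout.period
        shifted = SurfacePatches.concat([
            horizontal_lamina(area=0.02, z=0.02, x=0.04 + Lx),
            horizontal_lamina(area=0.03, z=0.05, x=-0.06 + Lx, y=0.1),
        ])
        s0 = compute_light(patches, layout, small_source,
                           np.random.default_rng(7))
        s1 = compute_light(shifted, layout, small_source,
                           np.random.default_rng(7))
        np.testing.assert_allclose(s0.absorbed, s1.absorbed, rtol=1e-12)
        np.testing.assert_allclose(s0.perceived, s1.perceived, rtol=1e-12)


class TestDose:
    def test_reference_dose(self):
        assert daily_par_dose(220.0, 9.0) == pytest.approx(7.128)

    @pytest.mark.parametrize("flux,hours", [(0.0, 9.0), (220.0, 0.0)])
    def test_zero_inputs(self, flux, hours):
        assert daily_par_dose(flux, hours) == 0.0


class TestPlantAggregates:
    def test_mean_rfr_sums_before_ratio(self, layout, small_source):
        # two organs of one plant: intercepted-flux ratio, not ratio average
        p1 = horizontal_lamina(area=0.01, z=0.01, plant_index=0)
        p2 = horizontal_lamina(area=0.01, z=0.05, x=0.03, plant_index=0)
        sample = compute_light(SurfacePatches.concat([p1, p2]), layout,
                               small_source, np.random.default_rng(0))
        red = sample.incident[:, 0].sum()
        farred = sample.incident[:, 1].sum()
        assert mean_plant_rfr(sample, 0) == pytest.approx(red / farred)
        # an unshaded plant intercepts light at the source ratio
        solo = compute_light(p2, layout, small_source,
                             np.random.default_rng(0))
        assert mean_plant_rfr(solo, 0) == pytest.approx(2.3, rel=1e-9)

    def test_unknown_plant_rejected(self, layout, small_source):
        sample = compute_light(horizontal_lamina(), layout, small_source,
                               np.random.default_rng(0))
        with pytest.raises(ValueError):
            mean_plant_rfr(sample, 3)

    def test_lai_is_area_times_density(self):
        plant = Plant(position=(0, 0), strategy=PlasticityStrategy(0.0))
        plant.leaves = [
            Leaf(rank=1, emergence_day=0, azimuth=0, lamina_area=0.003),
            Leaf(rank=2, emergence_day=0, azimuth=137.5, lamina_area=0.002),
        ]
        assert compute_lai(plant, 400.0) == pytest.approx(2.0)
        plant.leaves[1].senesced = True
        assert compute_lai(plant, 400.0) == pytest.approx(1.2)
        plant.leaves = []
        assert compute_lai(plant, 400.0) == 0.0
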