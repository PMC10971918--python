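"""Phantom assembly: properties, region maps, arteries, stroke insertion."""

import numpy as np
import pytest

from cceit.geometry import Grid
from cceit.phantom import (ARTERY_ANGLES_DEG, REGION, RegionPropertyPriors,
                           apply_stroke, artery_lines, assign_region_properties,
                           build_healthy_phantom, insert_stroke, sample_stroke)
from cceit.sampler import sample_geometry


class TestRegionProperties:
    def test_zero_sd_returns_table_means(self):
        priors = RegionPropertyPriors(
            skull_skin=(14.79, 0.0, 102.0, 0.0),
            brain=(46.46, 0.0, 378.0, 0.0),
            csf=(61.26, 0.0, 788.0, 0.0))
        p = assign_region_properties(priors, rng_seed=0)
        assert p.brain_left == (46.46, 378.0)
        assert p.brain_right == (46.46, 378.0)
        assert p.csf == (61.26, 788.0)
        assert p.skull_skin == (14.79, 102.0)

    def test_ordering_enforced_on_every_draw(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = assign_region_properties(rng_seed=rng)
            for k in (0, 1):  # eps then sigma
                assert p.csf[k] > max(p.brain_left[k], p.brain_right[k])
                assert min(p.brain_left[k], p.brain_right[k]) > p.skull_skin[k]

    def test_brain_sigma_monte_carlo_mean(self):
        """1000 draws: the brain-sigma sample mean stays within 3 standard
        errors of the 378 mS/m prior mean (the ordering constraint rarely
        binds for these priors)."""
        rng = np.random.default_rng(17)
        vals = [assign_region_properties(rng_seed=rng).brain_left[1]
                for _ in range(1000)]
        assert abs(np.mean(vals) - 378.0) <= 3.0 * 59.0 / np.sqrt(1000)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            RegionPropertyPriors(brain=(-1.0, 1.0, 378.0, 59.0))


class TestHealthyPhantom:
    def test_labels_partition_grid(self, phantom):
        assert phantom.region_map.dtype == np.uint8
        assert set(np.unique(phantom.region_map)) <= set(REGION.values())
        assert phantom.condition == "healthy" and phantom.stroke is None

    def test_centre_pixel_is_brain_or_csf(self, phantom):
        n = phantom.grid.n
        centre = phantom.region_map[n // 2, n // 2]
        assert centre in (REGION["brain_left"], REGION["brain_right"], REGION["csf"])

    def test_background_is_free_space(self, phantom):
        outside = phantom.region_map == REGION["outside"]
        assert np.all(phantom.sigma_map[outside] == 0.0)
        assert np.all(phantom.eps_map[outside] == 1.0)

    def test_maps_piecewise_constant_on_labels(self, phantom):
        for code in np.unique(phantom.region_map):
            sel = phantom.region_map == code
            assert np.unique(phantom.sigma_map[sel]).size <= 2  # left/right share prior
            assert np.unique(phantom.eps_map[sel]).size <= 2

    def test_property_ordering_in_maps(self, phantom):
        sig = phantom.sigma_map
        reg = phantom.region_map
        assert sig[reg == REGION["csf"]].mean() > sig[reg == REGION["brain_left"]].mean()
        assert sig[reg == REGION["brain_left"]].mean() > sig[reg == REGION["skull"]].mean()


class TestArteryLines:
    def test_angles_match_the_artery_fan(self, geometry):
        _, rays = artery_lines(geometry)
        assert [a for a, _ in rays] == list(ARTERY_ANGLES_DEG)

    def test_plus_minus_rays_mirror_about_vertical(self, geometry):
        _, rays = artery_lines(geometry)
        d = dict(rays)
        for ang in (12.0, 80.0, 135.0):
            dx_p, dy_p = d[ang]
            dx_m, dy_m = d[-ang]
            assert dx_p == pytest.approx(-dx_m)
            assert dy_p == pytest.approx(dy_m)

    def test_anchor_on_inner_vertical_axis(self, geometry):
        (ax, ay), _ = artery_lines(geometry)
        inner = geometry.inner
        t = np.deg2rad(inner.tilt)
        assert ax == pytest.approx(inner.center_x - np.sin(t) * inner.semi_b / 2)
        assert ay == pytest.approx(inner.center_y + np.cos(t) * inner.semi_b / 2)

    def test_every_ray_crosses_the_brain_raster(self, tables):
        """Rasterisation oracle: each artery ray hits at least one brain
        pixel at 256^2 for 100 sampled phantoms."""
        grid = Grid(tables.image_extent, 256)
        X, Y = grid.xy
        half, px = grid.extent_mm / 2.0, grid.pixel_mm
        for seed in range(100):
            g = sample_geometry(tables, rng_seed=3000 + seed)
            m = g.masks(grid)
            brain = m["brain_left"] | m["brain_right"]
            (ax, ay), rays = artery_lines(g)
            ts = np.arange(0.0, 200.0, px / 2.0)
            for ang, (dx, dy) in rays:
                xs, ys = ax + ts * dx, ay + ts * dy
                cols = np.floor((xs + half) / px).astype(int)
                rows = np.floor((half - ys) / px).astype(int)
                ok = (cols >= 0) & (cols < 256) & (rows >= 0) & (rows < 256)
                assert brain[rows[ok], cols[ok]].any(), (seed, ang)


class TestStroke:
    @pytest.fixture(scope="class")
    def hemorrhagic(self, phantom):
        return insert_stroke(phantom, "hemorrhagic", rng_seed=21)

    @pytest.fixture(scope="class")
    def ischemic(self, phantom):
        return insert_stroke(phantom, "ischemic", rng_seed=22)

    def test_hemorrhagic_lesion_is_blood(self, hemorrhagic):
        les = hemorrhagic.region_map == REGION["lesion"]
        assert les.any()
        assert np.all(hemorrhagic.sigma_map[les] == 1230.0)
        assert np.all(hemorrhagic.eps_map[les] == 76.0)

    def test_ischemic_sigma_fraction_of_host(self, ischemic, properties):
        host = (properties.brain_left if ischemic.stroke.hemisphere == "left"
                else properties.brain_right)
        ratio = ischemic.stroke.sigma_lesion / host[1]
        assert 0.60 <= ratio <= 0.70
        les = ischemic.region_map == REGION["lesion"]
        assert np.all(ischemic.eps_map[les] == host[0])

    @pytest.mark.parametrize("kind", ["hemorrhagic", "ischemic"])
    def test_lesion_avoids_csf_and_stays_in_one_hemisphere(self, phantom, kind):
        ph = insert_stroke(phantom, kind, rng_seed=5)
        les = ph.region_map == REGION["lesion"]
        healthy = phantom.region_map
        assert not (les & (healthy == REGION["csf"])).any()
        host = REGION["brain_left" if ph.stroke.hemisphere == "left" else "brain_right"]
        assert np.all(healthy[les] == host)

    def test_healthy_maps_restored_outside_lesion(self, phantom, hemorrhagic):
        les = hemorrhagic.region_map == REGION["lesion"]
        assert np.array_equal(hemorrhagic.sigma_map[~les], phantom.sigma_map[~les])
        assert np.array_equal(hemorrhagic.region_map[~les], phantom.region_map[~les])

    def test_hemorrhage_raises_and_ischemia_lowers_brain_sigma(
            self, phantom, hemorrhagic, ischemic):
        def brain_mean(ph):
            sel = np.isin(ph.region_map,
                          [REGION["brain_left"], REGION["brain_right"], REGION["lesion"]])
            return ph.sigma_map[sel].mean()

        base = brain_mean(phantom)
        assert brain_mean(hemorrhagic) > base
        assert brain_mean(ischemic) < base

    def test_radius_at_least_15_mm(self, hemorrhagic, ischemic):
        assert hemorrhagic.stroke.radius >= 15.0
        assert ischemic.stroke.radius >= 15.0

    def test_insertion_is_bit_reproducible(self, phantom):
        a = insert_stroke(phantom, "ischemic", rng_seed=9)
        b = insert_stroke(phantom, "ischemic", rng_seed=9)
        assert a.stroke == b.stroke
        assert np.array_equal(a.sigma_map, b.sigma_map)

    def test_stroke_only_into_healthy(self, hemorrhagic):
        with pytest.raises(ValueError):
            apply_stroke(hemorrhagic, hemorrhagic.stroke)

    def test_descriptor_is_grid_independent(self, geometry, properties):
        s1 = sample_stroke(geometry, properties, "hemorrhagic", rng_seed=4)
        s2 = sample_stroke(geometry, properties, "hemorrhagic", rng_seed=4)
        assert s1 == s2


def test_region_png_export(phantom, tmp_path):
    from cceit.phantom import export_region_png

    path = tmp_path / "regions.png"
    export_region_png(phantom, path)
    from PIL import Image

    img = Image.open(path)
    assert img.size == (64, 64)
    assert img.mode == "P"
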