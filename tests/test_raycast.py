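"""Diffuse-sky ray casting: oracles, energy bookkeeping, convergence."""

import numpy as np
import pytest

from conftest import poisson_leaf_scene
from lightshare.geometry import organ_tessellate
from lightshare.raycast import (
    diffuse_interception,
    directional_interception,
    species_share,
)
from lightshare.scene import Scene
from lightshare.sky import SkySector, SkyVault, build_sky
from lightshare.theory import extinction_directional


def _full_cover_scene(species="pea"):
    organs = [organ_tessellate(
        "stipule", 1000.0, 1000.0, 0.0, 0.0, np.array([0.5, 0.5, 0.2]),
        outline="rect", species=species,
    )]
    return Scene(organs=organs, plot_x=1.0, plot_y=1.0)


class TestDirectional:
    def test_empty_scene_all_soil(self):
        scene = Scene(organs=[], plot_x=1.0, plot_y=1.0)
        r = directional_interception(scene, 30.0, 120.0, n_rays=100, seed=0)
        assert r.fraction_soil == 1.0

    def test_full_cover_plate_intercepts_everything(self):
        r = directional_interception(_full_cover_scene(), 0.0, 0.0, n_rays=1000, seed=1)
        assert r.fraction_by_species["pea"] == 1.0
        assert r.fraction_soil == 0.0

    def test_full_cover_wraps_periodically_at_oblique_angles(self):
        # the plate tiles the footprint, so any direction is fully covered
        r = directional_interception(_full_cover_scene(), 72.0, 33.0, n_rays=1000, seed=1)
        assert r.fraction_by_species["pea"] == 1.0

    def test_beer_lambert_horizontal_leaves_vertical_beam(self):
        # mean over independent Poisson canopies vs the exact finite-leaf
        # expectation 1 - (1 - a/A)^N ~ 1 - e^-LAI
        vals, n_rays = [], 20_000
        reps = 12
        for s in range(reps):
            sc = poisson_leaf_scene(seed=100 + s, lai=1.0, leaf_mm=25.0)
            vals.append(
                directional_interception(sc, 0.0, 0.0, n_rays, seed=s)
                .fraction_by_species["pea"]
            )
        mean = np.mean(vals)
        stderr = np.std(vals, ddof=1) / np.sqrt(reps)
        expected = 1.0 - np.exp(-1.0)
        assert abs(mean - expected) < 3.0 * max(stderr, 1e-4)

    def test_energy_bookkeeping_exact(self):
        sc = poisson_leaf_scene(seed=7, lai=0.8)
        for zen, az in ((0.0, 0.0), (54.0, 45.0), (72.0, 290.0)):
            r = directional_interception(sc, zen, az, n_rays=5000, seed=3)
            total = sum(r.fraction_by_species.values()) + r.fraction_soil
            assert total == 1.0  # counting measure: exact

    def test_adding_organ_never_decreases_interception(self):
        sc = poisson_leaf_scene(seed=11, lai=0.5)
        base = directional_interception(sc, 36.0, 10.0, n_rays=20_000, seed=5)
        extra = organ_tessellate(
            "stipule", 60.0, 60.0, 20.0, 0.0, np.array([0.25, 0.25, 0.6]),
            outline="rect", species="pea",
        )
        bigger = Scene(organs=sc.organs + [extra], plot_x=sc.plot_x, plot_y=sc.plot_y)
        more = directional_interception(bigger, 36.0, 10.0, n_rays=20_000, seed=5)
        assert (
            more.fraction_by_species["pea"] >= base.fraction_by_species["pea"]
        )

    def test_invalid_inputs_rejected(self):
        sc = poisson_leaf_scene(seed=1, lai=0.2)
        with pytest.raises(ValueError):
            directional_interception(sc, 95.0, 0.0, n_rays=10, seed=0)
        with pytest.raises(ValueError):
            directional_interception(sc, 10.0, 0.0, n_rays=0, seed=0)


class TestDiffuse:
    def test_empty_scene(self):
        scene = Scene(organs=[], plot_x=1.0, plot_y=1.0)
        res = diffuse_interception(scene, build_sky(), 100, seed=0)
        assert res.fraction_soil == pytest.approx(1.0, abs=1e-12)

    def test_single_sector_vault_equals_directional(self):
        sc = poisson_leaf_scene(seed=3, lai=0.7)
        sky = SkyVault(sectors=(SkySector(zenith=36.0, azimuth=90.0, weight=1.0),))
        res = diffuse_interception(sc, sky, 10_000, seed=4)
        sub_seed = int(np.random.SeedSequence((4, 0)).generate_state(1)[0])
        direct = directional_interception(sc, 36.0, 90.0, 10_000, seed=sub_seed)
        assert res.fraction_by_species["pea"] == pytest.approx(
            direct.fraction_by_species["pea"], abs=1e-15
        )

    def test_weighted_sum_and_error_propagation(self):
        sc = poisson_leaf_scene(seed=5, lai=1.0)
        sky = build_sky()
        res = diffuse_interception(sc, sky, 2000, seed=6)
        manual = sum(
            d.weight * d.fraction_by_species["pea"] for d in res.per_direction
        )
        assert res.fraction_by_species["pea"] == pytest.approx(manual, abs=1e-12)
        assert res.mc_stderr["pea"] > 0

    def test_stderr_halves_when_rays_quadruple(self):
        sc = poisson_leaf_scene(seed=9, lai=1.0)
        sky = build_sky()
        e1 = diffuse_interception(sc, sky, 2000, seed=1).mc_stderr["pea"]
        e4 = diffuse_interception(sc, sky, 8000, seed=1).mc_stderr["pea"]
        assert e4 == pytest.approx(e1 / 2.0, rel=0.2)

    def test_turbid_medium_limit_over_sky_vault(self):
        # homogeneous horizontal-leaf canopies: diffuse interception matches
        # the Beer-Lambert prediction integrated over the same sky vault
        sky = build_sky()
        lai = 0.8
        k_dir = extinction_directional(0.0, sky.zeniths)
        expected = float(np.sum(sky.weights * -np.expm1(-k_dir * lai)))
        vals = []
        reps = 8
        for s in range(reps):
            sc = poisson_leaf_scene(seed=300 + s, lai=lai, leaf_mm=25.0)
            vals.append(
                diffuse_interception(sc, sky, 5000, seed=s).fraction_by_species["pea"]
            )
        stderr = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - expected) < 3.0 * max(stderr, 1e-3)


class TestShare:
    def test_arithmetic(self):
        sky = build_sky()
        half = poisson_leaf_scene(seed=21, lai=0.4, species="pea")
        other = poisson_leaf_scene(seed=22, lai=0.4, species="wheat")
        scene = Scene(
            organs=half.organs + other.organs, plot_x=half.plot_x, plot_y=half.plot_y
        )
        res = diffuse_interception(scene, sky, 20_000, seed=2)
        share = species_share(res)
        # statistically identical canopies: share near 1/2
        err = 3.0 * res.mc_stderr["pea"] / res.fraction_by_species["pea"] + 0.05
        assert share.pea_share == pytest.approx(0.5, abs=err)

    def test_zero_interception_rejected(self):
        res = diffuse_interception(
            Scene(organs=[], plot_x=1.0, plot_y=1.0), build_sky(), 100, seed=0
        )
        with pytest.raises(ValueError):
            species_share(res)
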