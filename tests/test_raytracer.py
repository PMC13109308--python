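import math

import numpy as np
import pytest
from scipy import stats

from leafbrdf import fixtures
from leafbrdf.cooktorrance import BRDFParams
from leafbrdf.raytracer import (
    CanopyMesh,
    MeshConfigurationError,
    PhotonSource,
    directional_hemispherical_reflectance,
    layer_summary,
    sample_scatter_direction,
    simulate,
)

DOWN = np.array([0.0, 0.0, -1.0])
UP = np.array([0.0, 0.0, 1.0])


def square(z, x0, y0, side):
    a = [x0, y0, z]
    b = [x0 + side, y0, z]
    c = [x0 + side, y0 + side, z]
    d = [x0, y0 + side, z]
    return [[a, b, c], [a, c, d]]


class TestHemisphericalReflectance:
    def test_perfect_lambertian_integrates_to_one(self):
        assert directional_hemispherical_reflectance(
            BRDFParams(0.5, 1.0, 1.0), 0.0
        ) == pytest.approx(1.0, abs=1e-9)

    def test_black_surface(self):
        assert directional_hemispherical_reflectance(
            BRDFParams(0.5, 0.0, 1.0), 0.3
        ) == pytest.approx(0.0, abs=1e-20)

    def test_diffuse_quadrature_matches_closed_form(self):
        for k in (0.05, 0.35, 0.8):
            for ti in (0.0, math.radians(30), math.radians(60)):
                R = directional_hemispherical_reflectance(BRDFParams(0.4, k, 1.0), ti)
                assert R == pytest.approx(k, abs=1e-4)

    def test_quadrature_resolution_guard(self):
        with pytest.raises(ValueError):
            directional_hemispherical_reflectance(BRDFParams(0.3, 0.3, 2.0), 0.0, n_quad=4)

    def test_specular_adds_energy_and_stays_physical(self):
        base = directional_hemispherical_reflectance(BRDFParams(0.3, 0.35, 1.0), 0.4)
        withspec = directional_hemispherical_reflectance(BRDFParams(0.3, 0.35, 2.2), 0.4)
        assert withspec > base
        assert withspec <= 1.0


class TestScatterSampling:
    def test_black_facet_always_absorbs(self):
        rng = np.random.default_rng(0)
        p = BRDFParams(0.5, 0.0, 1.0)
        for _ in range(100):
            event, d = sample_scatter_direction(p, 0.0, DOWN, UP, rng, reflectance=0.0)
            assert event == "absorb" and d is None

    def test_lambertian_reflection_is_cosine_weighted(self):
        # under cosine weighting the CDF of mu=cos(theta) is mu^2:
        # transformed samples must be uniform (chi-square on 10 bins)
        rng = np.random.default_rng(42)
        p = BRDFParams(0.3, 1.0, 1.0)
        mus = []
        for _ in range(10000):
            event, d = sample_scatter_direction(p, 0.0, DOWN, UP, rng, reflectance=1.0)
            assert event == "reflect"
            assert d[2] > 0  # stays in the exit hemisphere
            mus.append(d[2])
        counts, _ = np.histogram(np.array(mus) ** 2, bins=10, range=(0, 1))
        chi2 = float(((counts - 1000) ** 2 / 1000).sum())
        assert 1 - stats.chi2.cdf(chi2, 9) > 0.01

    def test_specular_lobe_centers_on_mirror_direction(self):
        rng = np.random.default_rng(3)
        p = BRDFParams(0.2, 0.01, 2.2)
        incident = np.array([math.sin(0.6), 0.0, -math.cos(0.6)])
        mirror = incident - 2 * (incident @ UP) * UP
        dots = []
        for _ in range(2000):
            event, d = sample_scatter_direction(p, 0.0, incident, UP, rng, reflectance=0.2)
            if event == "reflect":
                dots.append(d @ mirror)
        # most non-diffuse samples concentrate near the mirror direction
        assert np.median(dots) > 0.8

    def test_transmission_goes_into_far_hemisphere(self):
        rng = np.random.default_rng(5)
        p = BRDFParams(0.3, 0.0, 1.0)
        events = set()
        for _ in range(200):
            event, d = sample_scatter_direction(p, 0.5, DOWN, UP, rng, reflectance=0.0)
            events.add(event)
            if event == "transmit":
                assert d[2] < 0
        assert events == {"transmit", "absorb"}

    def test_seeded_stream_is_reproducible(self):
        p = BRDFParams(0.3, 0.5, 2.2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            seq = [
                sample_scatter_direction(p, 0.1, DOWN, UP, rng, reflectance=0.5)
                for _ in range(50)
            ]
            out.append(seq)
        for (e1, d1), (e2, d2) in zip(*out):
            assert e1 == e2
            if d1 is not None:
                assert np.array_equal(d1, d2)


class TestMesh:
    def test_overunity_energy_rejected_at_load(self):
        tris = np.array(square(0.5, 0, 0, 1.0))
        optics = np.array([[0.3, 1.0, 1.0, 0.5]] * 2)  # R=1 plus tau=0.5
        mesh = CanopyMesh(tris, optics)
        with pytest.raises(MeshConfigurationError):
            simulate(mesh, PhotonSource(n_photons=10, seed=0))

    def test_degenerate_triangles_rejected(self):
        tris = np.zeros((1, 3, 3))
        with pytest.raises(ValueError):
            CanopyMesh(tris, np.array([[0.3, 0.3, 1.0, 0.0]]))


class TestSimulate:
    def test_black_canopy_scatters_nothing(self):
        mesh = fixtures.synth_canopy(2, 10, optics=(0.3, 0.0, 1.0), tau=0.0, seed=1)
        res = simulate(mesh, PhotonSource(n_photons=2000, seed=2))
        assert np.all(res.facet_scattered_ppfd == 0)
        assert res.ledger.exited + res.ledger.absorbed == 2000

    def test_empty_mesh_everything_exits(self):
        mesh = CanopyMesh(np.zeros((0, 3, 3)), np.zeros((0, 4)))
        res = simulate(mesh, PhotonSource(n_photons=500, seed=0))
        assert res.ledger.exited == 500

    def test_photon_ledger_conserves_exactly(self):
        mesh = fixtures.synth_canopy(3, 25, optics=(0.3, 0.35, 2.2), tau=0.05, seed=4)
        res = simulate(mesh, PhotonSource(n_photons=3000, seed=5))
        led = res.ledger
        assert led.absorbed + led.exited + led.terminated == led.emitted == 3000

    def test_scattered_ppfd_scales_with_source(self):
        mesh = fixtures.synth_canopy(2, 20, optics=(0.3, 0.35, 1.0), seed=6)
        a = simulate(mesh, PhotonSource(ppfd=500, n_photons=2000, seed=7))
        b = simulate(mesh, PhotonSource(ppfd=1500, n_photons=2000, seed=7))
        assert b.facet_scattered_ppfd == pytest.approx(3 * a.facet_scattered_ppfd, rel=1e-12)

    def test_sigma_irrelevant_for_lambertian_facets(self):
        a = fixtures.synth_canopy(2, 20, optics=(0.3, 0.4, 1.0), seed=8)
        b = fixtures.synth_canopy(2, 20, optics=(0.9, 0.4, 1.0), seed=8)
        ra = simulate(a, PhotonSource(n_photons=2000, seed=9))
        rb = simulate(b, PhotonSource(n_photons=2000, seed=9))
        assert np.array_equal(ra.facet_scattered_ppfd, rb.facet_scattered_ppfd)

    def test_two_plate_flux_matches_view_factor_oracle(self):
        # Lambertian floor, small absorbing receiver half a meter above it;
        # the scattered flux on the receiver equals the reflected flux times
        # the floor-to-receiver view factor (midpoint quadrature oracle)
        side, z_rec = 0.3, 0.5
        tris = square(0.0, 0, 0, 1.0) + square(z_rec, 0.35, 0.35, side)
        optics = [[0.3, 1.0, 1.0, 0.0]] * 2 + [[0.3, 0.0, 1.0, 0.0]] * 2
        mesh = CanopyMesh(np.array(tris, float), np.array(optics, float))
        n = 40000
        res = simulate(mesh, PhotonSource(ppfd=1000.0, n_photons=n, seed=3))
        w = 1000.0 / n
        scat_flux = float(np.sum(res.facet_scattered_ppfd[2:] * mesh.areas[2:]))

        gx = (np.arange(120) + 0.5) / 120
        fy, fx = np.meshgrid(gx, gx, indexing="ij")
        shadow = (fx > 0.35) & (fx < 0.65) & (fy > 0.35) & (fy < 0.65)
        r = 0.35 + (np.arange(20) + 0.5) * side / 20
        RX, RY = np.meshgrid(r, r, indexing="ij")
        F = np.zeros_like(fx)
        for i in range(fx.shape[0]):
            dx = RX[None] - fx[i][:, None, None]
            dy = RY[None] - fy[i][:, None, None]
            r2 = dx**2 + dy**2 + z_rec**2
            F[i] = (z_rec**2 / (math.pi * r2**2)).sum(axis=(1, 2)) * (side / 20) ** 2
        p_hit = (~shadow).mean() * F[~shadow].mean()
        expected = w * n * p_hit
        se = w * math.sqrt(n * p_hit * (1 - p_hit))
        assert abs(scat_flux - expected) <= 3 * se

    def test_montecarlo_layer_means_converge(self):
        # five independent 1e4-photon runs give an empirical standard error
        # per layer; their mean must sit within ~3 SE of a 5e4-photon run
        mesh = fixtures.synth_canopy(3, 20, optics=(0.3, 0.35, 1.0), seed=10)
        small = np.array(
            [
                layer_summary(
                    mesh,
                    simulate(mesh, PhotonSource(n_photons=10000, seed=100 + s)).facet_scattered_ppfd,
                    3,
                ).mean_scattered_ppfd
                for s in range(5)
            ]
        )
        big = layer_summary(
            mesh, simulate(mesh, PhotonSource(n_photons=50000, seed=999)).facet_scattered_ppfd, 3
        ).mean_scattered_ppfd
        mean_small = small.mean(axis=0)
        se_mean = small.std(axis=0, ddof=1) / math.sqrt(5)
        # both estimates are means of ~5e4 photons: difference SE ~ sqrt(2)*se_mean
        tol = 3 * math.sqrt(2) * se_mean + 1e-9
        assert np.all(np.abs(mean_small - big) <= tol)


class TestLayerSummary:
    def test_single_layer_equals_global_mean(self):
        mesh = fixtures.synth_canopy(2, 15, seed=13)
        ppfd = np.random.default_rng(0).uniform(0, 100, mesh.n_facets)
        prof = layer_summary(mesh, ppfd, 1)
        assert prof.mean_scattered_ppfd[0] == pytest.approx(
            np.average(ppfd, weights=mesh.areas)
        )

    def test_empty_bottom_layer_reads_zero(self):
        tris = np.array(square(0.9, 0, 0, 1.0) + square(0.8, 0, 0, 1.0), float)
        optics = np.tile([0.3, 0.3, 1.0, 0.0], (4, 1))
        mesh = CanopyMesh(tris, optics)
        # stretch bounds downward with a tiny facet at z=0
        tris2 = np.vstack([tris, np.array(square(0.0, 0, 0, 0.01), float)])
        optics2 = np.tile([0.3, 0.3, 1.0, 0.0], (6, 1))
        mesh2 = CanopyMesh(tris2, optics2)
        ppfd = np.array([10.0, 10.0, 20.0, 20.0, 0.0, 0.0])
        prof = layer_summary(mesh2, ppfd, 2)
        assert prof.mean_scattered_ppfd[0] == pytest.approx(0.0)
        assert prof.mean_scattered_ppfd[1] > 0

    def test_histogram_uses_intensity_bins(self):
        mesh = fixtures.synth_canopy(1, 10, seed=14)
        ppfd = np.array([5, 50, 90, 200, 10, 45, 85, 120, 30, 160], dtype=float)
        prof = layer_summary(mesh, ppfd, 1)
        assert prof.histogram.tolist() == [3, 2, 3, 2]
        assert prof.histogram.sum() == mesh.n_facets
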