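import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from leafbrdf.cooktorrance import (
    BRDFParams,
    beckmann,
    brdf_eval_arrays,
    brdf_value,
    fresnel,
    geometric_attenuation,
)
from leafbrdf.geometry import DegenerateGeometryError, InstrumentAngles, geometry_frame


def frame(theta_i, theta_v, phi_v=0.0):
    return geometry_frame(
        InstrumentAngles(view_zenith_deg=theta_v, view_azimuth_deg=phi_v, incident_zenith_deg=theta_i)
    )


class TestParams:
    def test_bounds_enforced(self):
        BRDFParams(0.0, 0.0, 1.0)
        BRDFParams(1.0, 1.0, 5.0)
        for bad in [(-0.1, 0.5, 2.0), (0.5, 1.2, 2.0), (0.5, 0.5, 0.9), (0.5, 0.5, 5.1)]:
            with pytest.raises(ValueError):
                BRDFParams(*bad)


class TestFresnel:
    def test_index_matched_medium_reflects_nothing(self):
        assert fresnel(1.0, 0.8) == pytest.approx(0.0, abs=1e-12)

    def test_normal_incidence_closed_form(self):
        # ((n-1)/(n+1))^2 at cos = 1
        assert fresnel(1.5, 1.0) == pytest.approx(0.04, abs=1e-12)
        for n in (1.1, 2.2, 3.7, 5.0):
            assert fresnel(n, 1.0) == pytest.approx(((n - 1) / (n + 1)) ** 2, abs=1e-12)

    def test_grazing_limit_is_total(self):
        assert fresnel(2.2, 0.0) == pytest.approx(1.0, abs=1e-12)
        assert fresnel(2.2, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_rises_to_total_reflection_at_grazing(self):
        # unpolarized reflectance is not strictly monotone: the parallel
        # component's Brewster zero carves a shallow dip (deeper for large n)
        # before the curve climbs to 1 at grazing
        cos_grid = np.linspace(1.0, 1e-6, 400)
        for n in (1.05, 1.5, 2.2, 4.0):
            F = fresnel(n, cos_grid)
            assert np.all((F >= 0) & (F <= 1))
            assert F[-1] == pytest.approx(1.0, abs=1e-3)
            i_min = int(np.argmin(F))
            assert F[i_min] >= F[0] - 5e-3  # the dip is shallow
            assert np.all(np.diff(F[i_min:]) >= -1e-12)  # monotone past the dip

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fresnel(0.9, 0.5)
        with pytest.raises(ValueError):
            fresnel(1.5, 1.5)


class TestBeckmann:
    @pytest.mark.parametrize(
        "alpha,sigma,expected",
        [(0.0, 0.5, 4.0), (0.0, 1.0, 1.0), (math.atan(0.3), 0.3, 4.8564)],
    )
    def test_values(self, alpha, sigma, expected):
        assert beckmann(alpha, sigma) == pytest.approx(expected, rel=1e-4)

    def test_matches_direct_formula_on_grid(self):
        alphas = np.linspace(0.0, math.pi / 2 - 0.05, 100)
        for sigma in (0.1, 0.3, 0.7, 1.0):
            expected = np.exp(-((np.tan(alphas) / sigma) ** 2)) / (sigma**2 * np.cos(alphas) ** 4)
            assert beckmann(alphas, sigma) == pytest.approx(expected)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            beckmann(math.pi / 2, 0.5)
        with pytest.raises(ValueError):
            beckmann(0.1, 0.0)


class TestGeometricAttenuation:
    def test_coincident_frame(self):
        assert geometric_attenuation(frame(0.0, 0.0)) == pytest.approx(1.0)

    def test_specular_45_in_plane(self):
        # H = N for the mirror geometry: 2*cos45*1/cos45 = 2 -> min with 1
        assert geometric_attenuation(frame(45.0, 90.0)) == pytest.approx(1.0)

    def test_bounded_by_one(self, rng):
        for _ in range(50):
            fr = frame(rng.uniform(-60, 60), rng.uniform(-5, 85), rng.uniform(0, 360))
            if fr.degenerate or fr.cos_VH <= 0:
                continue
            g = geometric_attenuation(fr)
            assert 0.0 < g <= 1.0

    def test_degenerate_frame_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            geometric_attenuation(frame(0.0, 170.0))


class TestBRDFValue:
    def test_lambertian_limit_is_inverse_pi(self):
        p = BRDFParams(0.5, 1.0, 1.0)
        for tv in (0.0, 20.0, 45.0, 80.0):
            assert brdf_value(p, frame(0.0, tv)) == pytest.approx(1 / math.pi, abs=1e-9)
        assert brdf_value(BRDFParams(0.35, 0.35, 1.0), frame(30.0, 10.0)) == pytest.approx(
            0.111408, abs=1e-5
        )

    @given(
        k=st.floats(min_value=0.0, max_value=1.0),
        sigma=st.floats(min_value=0.05, max_value=1.0),
        tv=st.floats(min_value=-5.0, max_value=80.0),
    )
    def test_unit_index_kills_specular_everywhere(self, k, sigma, tv):
        p = BRDFParams(sigma, k, 1.0)
        assert brdf_value(p, frame(10.0, tv)) == pytest.approx(k / math.pi, abs=1e-12)

    def test_term_by_term_oracle_at_specular_geometry(self):
        # independent evaluation: each factor computed from its printed
        # formula with plain math, then assembled
        fr = frame(30.0, 60.0)
        sigma, k, n = 0.3, 0.01, 2.2
        c = fr.cos_theta_h
        g = math.sqrt(n * n + c * c - 1.0)
        F = 0.5 * ((g - c) / (g + c)) ** 2 * (
            1 + ((c * (g + c) - 1) / (c * (g - c) + 1)) ** 2
        )
        D = math.exp(-((math.tan(fr.alpha) / sigma) ** 2)) / (sigma**2 * math.cos(fr.alpha) ** 4)
        G = min(
            1.0,
            2 * fr.cos_NV * fr.cos_NH / fr.cos_VH,
            2 * fr.cos_LN * fr.cos_NH / fr.cos_VH,
        )
        expected = F * D * G / (2 * math.pi**2 * fr.cos_LN * fr.cos_NV) + k / math.pi
        assert brdf_value(BRDFParams(sigma, k, n), fr) == pytest.approx(expected, rel=1e-12)

    def test_conventions_rescale_specular_only(self):
        p = BRDFParams(0.3, 0.2, 2.2)
        fr = frame(30.0, 60.0)
        diffuse = p.k / math.pi
        spec_printed = brdf_value(p, fr, "as_printed") - diffuse
        spec_pi = brdf_value(p, fr, "pi") - diffuse
        spec_four = brdf_value(p, fr, "four") - diffuse
        assert spec_pi == pytest.approx(spec_printed * 2 * math.pi, rel=1e-12)
        assert spec_four == pytest.approx(spec_printed * 2 * math.pi**2 / 4, rel=1e-12)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            brdf_value(BRDFParams(0.3, 0.2, 2.2), frame(30.0, 60.0), "bogus")

    def test_degenerate_frame_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            brdf_value(BRDFParams(0.3, 0.2, 2.2), frame(0.0, 170.0))

    def test_floor_is_diffuse_term(self, rng):
        for _ in range(30):
            p = BRDFParams(rng.uniform(0.05, 1), rng.uniform(0, 1), rng.uniform(1, 5))
            fr = frame(rng.uniform(-60, 60), rng.uniform(-5, 85))
            if fr.degenerate:
                continue
            assert brdf_value(p, fr) >= p.k / math.pi - 1e-12

    def test_smooth_in_each_parameter(self):
        fr = frame(30.0, 55.0)
        arrays = dict(
            cos_LN=np.array([fr.cos_LN]),
            cos_NV=np.array([fr.cos_NV]),
            cos_NH=np.array([fr.cos_NH]),
            cos_VH=np.array([fr.cos_VH]),
            cos_theta_h=np.array([fr.cos_theta_h]),
            alpha=np.array([fr.alpha]),
        )

        def f(s, k, n):
            return float(brdf_eval_arrays(s, k, n, **arrays)[0])

        # a small step in any parameter moves the value proportionally: no
        # jumps on the open parameter box
        h = 1e-5
        for s, k, n in [(0.3, 0.4, 2.0), (0.7, 0.1, 3.5)]:
            base = f(s, k, n)
            for ds_, dk, dn in [(h, 0, 0), (0, h, 0), (0, 0, h)]:
                step = abs(f(s + ds_, k + dk, n + dn) - base)
                assert step < 1e-3 * max(1.0, abs(base))


def test_array_kernel_matches_scalar_path(rng):
    from leafbrdf.geometry import scan_frame_arrays

    tl = rng.uniform(-50, 50, 40)
    tv = rng.uniform(-5, 85, 40)
    arr = scan_frame_arrays(tl, tv, 0.0)
    p = BRDFParams(0.25, 0.3, 2.5)
    vals = brdf_eval_arrays(
        p.sigma, p.k, p.n,
        arr["cos_LN"], arr["cos_NV"], arr["cos_NH"],
        arr["cos_VH"], arr["cos_theta_h"], arr["alpha"],
    )
    for i in np.flatnonzero(arr["usable"]):
        fr = frame(tl[i], tv[i])
        assert vals[i] == pytest.approx(brdf_value(p, fr), rel=1e-12)
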