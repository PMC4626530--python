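"""Closed-form image-series potentials against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from meafield import (
    GeometryError,
    LineSource,
    PointSource,
    SingularityError,
    SliceGeometry,
    UnsupportedConfigurationError,
    moi_line_mea_plane,
    moi_point_anisotropic_mea_plane,
    moi_point_general,
    moi_point_mea_plane,
    phi_homogeneous_line,
    phi_homogeneous_point,
    reflection_coefficient,
    rms_signal,
)


class TestReflectionCoefficient:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            (0.3, 1.5, -2.0 / 3.0),  # tissue under saline
            (0.7, 0.7, 0.0),  # identical media
            (0.3, 0.0, 1.0),  # perfect insulator below
        ],
    )
    def test_values(self, s1, s2, expected):
        assert reflection_coefficient(s1, s2) == pytest.approx(expected, abs=1e-15)

    def test_two_insulators_is_an_error(self):
        with pytest.raises(GeometryError):
            reflection_coefficient(0.0, 0.0)

    @given(
        s1=st.floats(1e-6, 1e3), s2=st.floats(1e-6, 1e3)
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounded_and_antisymmetric(self, s1, s2):
        w = reflection_coefficient(s1, s2)
        assert -1.0 <= w <= 1.0
        assert w == pytest.approx(-reflection_coefficient(s2, s1), abs=1e-15)


class TestHomogeneousPoint:
    def test_value_1na_at_100um(self):
        # I / (4 pi sigma r) for 1 nA, 0.3 S/m, 100 um -> 2.6526 uV
        phi = phi_homogeneous_point((100e-6, 0.0, 0.0), 0.3, 1e-9)
        assert phi == pytest.approx(2.6526e-6, rel=1e-4)

    def test_inverse_distance_scaling(self):
        p1 = phi_homogeneous_point((50e-6, 30e-6, 20e-6), 0.3, 1e-9)
        p2 = phi_homogeneous_point((100e-6, 60e-6, 40e-6), 0.3, 1e-9)
        assert p1 == pytest.approx(2.0 * p2, rel=1e-12)

    def test_spherical_symmetry(self, rng):
        r = 120e-6
        for _ in range(20):
            v = rng.normal(size=3)
            v *= r / np.linalg.norm(v)
            assert phi_homogeneous_point(v, 0.3, 1e-9) == pytest.approx(
                phi_homogeneous_point((r, 0, 0), 0.3, 1e-9), rel=1e-12
            )

    def test_zero_distance_raises(self):
        with pytest.raises(SingularityError):
            phi_homogeneous_point((0.0, 0.0, 0.0), 0.3, 1e-9)


class TestPointMeaPlane:
    def test_semi_infinite_slice_doubles_potential(self, semi_infinite):
        src = PointSource((10e-6, -20e-6, 120e-6), 3e-9)
        obs = (200e-6, 50e-6)
        expected = 2.0 * phi_homogeneous_point(
            (obs[0] - 10e-6, obs[1] + 20e-6, -120e-6), 0.3, 3e-9
        )
        assert moi_point_mea_plane(src, obs, semi_infinite) == pytest.approx(
            expected, rel=1e-14
        )

    def test_lateral_confinement_by_saline(self, geo):
        # Saline cover makes the lead field lateral profile steep:
        # <5% at 600 um offset for a 50 um-high source, ~20% for 250 um.
        for z, lo, hi in [(50e-6, 0.0, 0.05), (250e-6, 0.15, 0.25)]:
            src = PointSource((0, 0, z), 1e-9)
            ratio = moi_point_mea_plane(src, (600e-6, 0.0), geo) / moi_point_mea_plane(
                src, (0.0, 0.0), geo
            )
            assert lo < ratio < hi

    def test_truncation_within_analytic_tail_bound(self, rng):
        # The n-th image pair is bounded by 2 |W|^n phi_h(2nh - h); the
        # 20-term truncation error must respect the summed tail bound on
        # randomised geometries with |W_TS| <= 2/3.
        for _ in range(100):
            h = rng.uniform(100e-6, 600e-6)
            sigma_t = rng.uniform(0.1, 1.0)
            sigma_s = rng.uniform(sigma_t / 5.0, 5.0 * sigma_t)
            g = SliceGeometry(h=h, sigma_T=sigma_t, sigma_S=sigma_s, n_terms=20)
            assert abs(g.W_TS) <= 2.0 / 3.0 + 1e-12
            src = PointSource(
                (rng.normal(0, 1e-4), rng.normal(0, 1e-4), rng.uniform(0.05, 0.95) * h),
                1e-9,
            )
            obs = (rng.normal(0, 3e-4), rng.normal(0, 3e-4))
            approx = moi_point_mea_plane(src, obs, g)
            oracle = moi_point_mea_plane(src, obs, g, n_terms=1000)
            w = abs(g.W_TS)
            # each order n carries coefficient 2 W^n times two image
            # kernels, each bounded by phi_h at the closest image distance
            tail_bound = sum(
                4.0 * w**n * phi_homogeneous_point((0, 0, 2 * n * h - h), sigma_t, 1e-9)
                for n in range(21, 1001)
            )
            # 1e-12 relative slack absorbs float accumulation over the
            # 1000-term oracle when the analytic tail is negligible
            assert abs(approx - oracle) <= tail_bound + 1e-12 * abs(oracle)

    def test_adaptive_mode_matches_long_series(self, geo):
        src = PointSource((0, 0, 150e-6), 1e-9)
        adaptive = moi_point_mea_plane(src, (50e-6, 0.0), geo, n_terms="adaptive")
        oracle = moi_point_mea_plane(src, (50e-6, 0.0), geo, n_terms=1000)
        assert adaptive == pytest.approx(oracle, rel=1e-11)

    def test_superposition(self, geo, rng):
        sources = [
            PointSource(
                (rng.normal(0, 1e-4), rng.normal(0, 1e-4), rng.uniform(10e-6, 290e-6)),
                rng.normal(0, 1e-9),
            )
            for _ in range(5)
        ]
        obs = (40e-6, -70e-6)
        total = sum(moi_point_mea_plane(s, obs, geo) for s in sources)
        merged = sum(
            moi_point_mea_plane(PointSource(s.position, s.current), obs, geo)
            for s in sources
        )
        assert total == pytest.approx(merged, rel=1e-15)

    def test_circular_symmetry(self, geo, rng):
        src = PointSource((0, 0, 80e-6), 1e-9)
        d = 250e-6
        ref = moi_point_mea_plane(src, (d, 0.0), geo)
        for theta in rng.uniform(0, 2 * np.pi, size=10):
            obs = (d * np.cos(theta), d * np.sin(theta))
            assert moi_point_mea_plane(src, obs, geo) == pytest.approx(ref, rel=1e-12)

    def test_semi_infinite_limit_in_thickness(self):
        # As h grows, the bath images recede and phi -> 2 phi_h.
        src_z, obs = 50e-6, (100e-6, 0.0)
        target = 2.0 * phi_homogeneous_point((100e-6, 0.0, -src_z), 0.3, 1e-9)
        errs = []
        for h in (300e-6, 1e-3, 1e-2, 1e-1):
            g = SliceGeometry(h=h, sigma_T=0.3, sigma_S=1.5)
            phi = moi_point_mea_plane(PointSource((0, 0, src_z), 1e-9), obs, g)
            errs.append(abs(phi - target) / target)
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-3  # first image recedes only linearly with h

    def test_balanced_pair_decays_faster_than_monopole(self, geo):
        plus = PointSource((0, 0, 100e-6), 1e-9)
        minus = PointSource((30e-6, 0, 100e-6), -1e-9)
        distances = np.array([200e-6, 400e-6, 800e-6, 1600e-6])
        obs = np.column_stack([distances, np.zeros_like(distances)])
        pair = np.abs(
            moi_point_mea_plane(plus, obs, geo) + moi_point_mea_plane(minus, obs, geo)
        )
        mono = np.abs(moi_point_mea_plane(plus, obs, geo))
        rel = pair / mono
        assert np.all(np.diff(rel) < 0)

    def test_source_on_boundary_rejected(self, geo):
        for z in (0.0, geo.h):
            with pytest.raises(GeometryError):
                moi_point_mea_plane(PointSource((0, 0, z), 1e-9), (1e-4, 0.0), geo)

    def test_conductive_substrate_redirects_to_general(self, geo):
        g = SliceGeometry(h=300e-6, sigma_T=0.3, sigma_S=1.5, sigma_G=0.1)
        with pytest.raises(UnsupportedConfigurationError):
            moi_point_mea_plane(PointSource((0, 0, 1e-4), 1e-9), (1e-4, 0.0), g)


class TestPointGeneral:
    def test_all_media_equal_reduces_to_homogeneous(self):
        g = SliceGeometry(h=300e-6, sigma_T=0.3, sigma_S=0.3, sigma_G=0.3)
        src = PointSource((0, 0, 150e-6), 1e-9)
        obs = (50e-6, 20e-6, 100e-6)
        assert moi_point_general(src, obs, g) == pytest.approx(
            phi_homogeneous_point((50e-6, 20e-6, -50e-6), 0.3, 1e-9), rel=1e-14
        )

    def test_consistent_with_mea_plane_formula(self, geo):
        src = PointSource((0, 0, 150e-6), 1e-9)
        a = moi_point_general(src, (50e-6, 20e-6, 0.0), geo)
        b = moi_point_mea_plane(src, (50e-6, 20e-6), geo)
        assert a == pytest.approx(b, rel=1e-13)

    def test_converged_series_matches_1000_term_oracle(self):
        g400 = SliceGeometry(h=300e-6, sigma_T=0.3, sigma_S=1.5, n_terms=400)
        g1000 = SliceGeometry(h=300e-6, sigma_T=0.3, sigma_S=1.5, n_terms=1000)
        src = PointSource((0, 0, 150e-6), 1e-9)
        obs = (30e-6, -10e-6, 0.0)
        assert moi_point_general(src, obs, g400) == pytest.approx(
            moi_point_general(src, obs, g1000), rel=1e-12
        )

    def test_anisotropic_geometry_rejected(self):
        g = SliceGeometry(h=300e-6, sigma_T=(0.45, 0.3, 0.3), sigma_S=1.5)
        with pytest.raises(UnsupportedConfigurationError):
            moi_point_general(PointSource((0, 0, 1e-4), 1e-9), (0, 0, 0), g)

    def test_observation_outside_slice_rejected(self, geo):
        with pytest.raises(GeometryError):
            moi_point_general(
                PointSource((0, 0, 1e-4), 1e-9), (0.0, 0.0, geo.h * 1.5), geo
            )


class TestHomogeneousLine:
    def test_short_segment_approaches_point_source(self):
        line = LineSource((0, 0, 149.5e-6), (0, 0, 150.5e-6), 1e-9)
        obs = np.array([100e-6, 0.0, 150e-6])
        point = phi_homogeneous_point(obs - np.array([0, 0, 150e-6]), 0.3, 1e-9)
        assert phi_homogeneous_line(obs, line, 0.3) == pytest.approx(point, rel=1e-4)

    def test_matches_quadrature_of_point_kernel(self, rng):
        for _ in range(25):
            start = rng.uniform(-1e-4, 1e-4, 3) + np.array([0, 0, 2e-4])
            end = rng.uniform(-1e-4, 1e-4, 3) + np.array([0, 0, 2e-4])
            obs = rng.uniform(-3e-4, 3e-4, 3)
            if np.linalg.norm(obs - start) < 5e-5 or np.linalg.norm(obs - end) < 5e-5:
                continue
            line = LineSource(tuple(start), tuple(end), 1e-9)
            oracle, _ = quad(
                lambda s: phi_homogeneous_point(
                    obs - (start + s * (end - start)), 0.3, 1e-9
                ),
                0.0,
                1.0,
                limit=200,
            )
            assert phi_homogeneous_line(obs, line, 0.3) == pytest.approx(
                oracle, rel=1e-8
            )

    def test_endpoint_swap_invariance(self):
        a, b = (0, 0, 1e-4), (5e-5, 2e-5, 2e-4)
        obs = np.array([2e-4, -1e-4, 1.5e-4])
        assert phi_homogeneous_line(obs, LineSource(a, b, 1e-9), 0.3) == pytest.approx(
            phi_homogeneous_line(obs, LineSource(b, a, 1e-9), 0.3), rel=1e-12
        )

    def test_splitting_preserves_potential(self):
        a, b = np.array([0, 0, 1e-4]), np.array([8e-5, 0, 2e-4])
        mid = 0.5 * (a + b)
        obs = np.array([2e-4, 1e-4, 1.2e-4])
        whole = phi_homogeneous_line(obs, LineSource(tuple(a), tuple(b), 1e-9), 0.3)
        halves = phi_homogeneous_line(
            obs, LineSource(tuple(a), tuple(mid), 0.5e-9), 0.3
        ) + phi_homogeneous_line(obs, LineSource(tuple(mid), tuple(b), 0.5e-9), 0.3)
        assert halves == pytest.approx(whole, rel=1e-12)

    def test_observation_on_segment_raises(self):
        line = LineSource((0, 0, 1e-4), (0, 0, 2e-4), 1e-9)
        with pytest.raises(SingularityError):
            phi_homogeneous_line(np.array([0.0, 0.0, 1.5e-4]), line, 0.3)

    def test_on_axis_extension_is_finite(self):
        # Beyond the endpoints the axis is a regular location.
        line = LineSource((0, 0, 1e-4), (0, 0, 2e-4), 1e-9)
        val = phi_homogeneous_line(np.array([0.0, 0.0, 3e-4]), line, 0.3)
        assert np.isfinite(val) and val > 0


class TestLineMeaPlane:
    def test_semi_infinite_doubles_line_potential(self, semi_infinite):
        line = LineSource((0, 0, 1e-4), (6e-5, 0, 1.6e-4), 1e-9)
        obs = (2e-4, 1e-4)
        expected = 2.0 * phi_homogeneous_line(
            np.array([obs[0], obs[1], 0.0]), line, 0.3
        )
        assert moi_line_mea_plane(line, obs, semi_infinite) == pytest.approx(
            expected, rel=1e-14
        )

    def test_short_segment_matches_point_moi(self, geo):
        line = LineSource((0, 0, 149.5e-6), (0, 0, 150.5e-6), 1e-9)
        point = PointSource((0, 0, 150e-6), 1e-9)
        assert moi_line_mea_plane(line, (100e-6, 0.0), geo) == pytest.approx(
            moi_point_mea_plane(point, (100e-6, 0.0), geo), rel=1e-3
        )

    def test_matches_quadrature_of_point_moi_along_segment(self, geo, rng):
        for _ in range(10):
            start = np.array(
                [rng.normal(0, 1e-4), rng.normal(0, 1e-4), rng.uniform(5e-5, 2.5e-4)]
            )
            end = np.array(
                [rng.normal(0, 1e-4), rng.normal(0, 1e-4), rng.uniform(5e-5, 2.5e-4)]
            )
            line = LineSource(tuple(start), tuple(end), 1e-9)
            obs = (rng.normal(0, 2e-4), rng.normal(0, 2e-4))
            oracle, _ = quad(
                lambda s: moi_point_mea_plane(
                    PointSource(tuple(start + s * (end - start)), 1e-9), obs, geo
                ),
                0.0,
                1.0,
                limit=200,
            )
            assert moi_line_mea_plane(line, obs, geo) == pytest.approx(
                oracle, rel=1e-8
            )

    def test_segment_crossing_boundary_rejected(self, geo):
        line = LineSource((0, 0, 2e-4), (0, 0, 3.5e-4), 1e-9)
        with pytest.raises(GeometryError):
            moi_line_mea_plane(line, (1e-4, 0.0), geo)


class TestAnisotropicPoint:
    def test_isotropic_reduction(self, geo):
        src = PointSource((0, 0, 150e-6), 1e-9)
        obs = (120e-6, -60e-6)
        assert moi_point_anisotropic_mea_plane(src, obs, geo) == moi_point_mea_plane(
            src, obs, geo
        )

    def test_kernel_anisotropy_ratio(self):
        # phi along x over phi along y follows the anisotropy-weighted
        # metric sqrt((d^2 a + z'^2 a) / (d^2 + z'^2 a)) for each image.
        g = SliceGeometry(h=300e-6, sigma_T=(0.45, 0.3, 0.3), sigma_S=1.5, n_terms=0)
        alpha = g.alpha_a
        zp, d = 80e-6, 140e-6
        src = PointSource((0, 0, zp), 1e-9)
        phi_x = moi_point_anisotropic_mea_plane(src, (d, 0.0), g)
        phi_y = moi_point_anisotropic_mea_plane(src, (0.0, d), g)
        expected = np.sqrt((d**2 * alpha + zp**2 * alpha) / (d**2 + zp**2 * alpha))
        assert phi_x / phi_y == pytest.approx(expected, rel=1e-12)

    def test_anisotropic_reflection_coefficient(self):
        g = SliceGeometry(h=300e-6, sigma_T=(0.45, 0.3, 0.3), sigma_S=(2.25, 1.5, 1.5))
        assert g.W_TS_a == pytest.approx(-2.0 / 3.0, abs=1e-15)

    def test_nonplanar_anisotropy_rejected(self):
        g = SliceGeometry(h=300e-6, sigma_T=(0.3, 0.3, 0.45), sigma_S=1.5)
        with pytest.raises(GeometryError):
            moi_point_anisotropic_mea_plane(
                PointSource((0, 0, 1e-4), 1e-9), (1e-4, 0.0), g
            )

    def test_warns_near_bath_interface(self):
        g = SliceGeometry(h=300e-6, sigma_T=(0.45, 0.3, 0.3), sigma_S=1.5)
        with pytest.warns(UserWarning, match="tissue-saline interface"):
            moi_point_anisotropic_mea_plane(
                PointSource((0, 0, 290e-6), 1e-9), (1e-4, 0.0), g
            )


class TestRms:
    def test_constant_signals(self):
        assert rms_signal([3.0, 3.0, 3.0]) == pytest.approx(3.0)

    def test_three_four(self):
        assert rms_signal([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_homogeneity(self, rng):
        v = rng.normal(size=30)
        assert rms_signal(-2.5 * v) == pytest.approx(2.5 * rms_signal(v), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_signal([])
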