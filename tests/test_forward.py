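import math

import numpy as np
import pytest

import fibrediff as fd
from fibrediff.forward import rot_x, rot_y, rot_z

from conftest import brute_force_intensity


class TestEwaldVector:
    def test_zero_q_maps_to_origin(self, beam14):
        assert np.allclose(fd.ewald_vector(0.0, 1.0, beam14), 0.0)

    def test_magnitude_preserved(self, beam14):
        rng = np.random.default_rng(0)
        q = rng.uniform(0.1, 25.0, 50)
        chi = rng.uniform(0, 2 * math.pi, 50)
        Q = fd.ewald_vector(q, chi, beam14)
        assert np.allclose(np.linalg.norm(Q, axis=-1), q, rtol=1e-14)

    def test_z_component_from_wavevector_construction(self, beam14):
        """Q_z from the explicit incoming/outgoing wavevector difference.

        With the beam along -z, k_in = -k zhat and k_out at scattering
        angle 2 theta; Q = k_out - k_in then has Q_z = + q^2 lambda/(4 pi).
        """
        k = beam14.k
        for q, chi in [(5.0, 0.3), (13.7, 2.0), (20.0, 5.5)]:
            theta = math.asin(q / (2 * k))
            k_in = np.array([0.0, 0.0, -k])
            k_out = k * np.array(
                [
                    math.sin(2 * theta) * math.cos(chi),
                    math.sin(2 * theta) * math.sin(chi),
                    -math.cos(2 * theta),
                ]
            )
            Q_oracle = k_out - k_in
            Q = fd.ewald_vector(q, chi, beam14)
            assert np.allclose(Q, Q_oracle, atol=1e-10)
            assert Q[2] == pytest.approx(q * q * beam14.wavelength_nm / (4 * math.pi))

    def test_beyond_backscattering_rejected(self, beam14):
        with pytest.raises(ValueError):
            fd.ewald_vector(2.0 * beam14.k, 0.0, beam14)


class TestFibreDirection:
    def test_axes(self):
        assert np.allclose(fd.fibre_direction(0.0, fd.Orientation(0, 0)), [1, 0, 0])
        assert np.allclose(
            fd.fibre_direction(math.pi / 2, fd.Orientation(0, 0)), [0, 1, 0]
        )
        assert np.allclose(
            fd.fibre_direction(0.0, fd.Orientation(0, math.pi / 2)), [0, 0, -1]
        )

    def test_matches_rotation_matrix_product(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            g, a, b = rng.uniform(-math.pi, math.pi, 3)
            n = fd.fibre_direction(g, fd.Orientation(a, b))
            oracle = rot_x(a) @ rot_y(b) @ rot_z(g) @ np.array([1.0, 0, 0])
            assert np.allclose(n, oracle, atol=1e-12)
            assert np.linalg.norm(n) == pytest.approx(1.0)


class TestSingleFibril:
    def test_axial_band_centre(self, rings):
        """(00l) with the fibre vertical: Q along the fibre axis sits at the
        band centre, intensity ~ N."""
        g = rings["002"]
        shape = fd.PeakShape(2.0, math.radians(5), g.q0_nominal, 0.3)
        n = np.array([0.0, 1.0, 0.0])
        I = fd.single_fibril_intensity(g.q0_nominal * n, n, g, shape)
        w2 = shape.w_mu**2
        expected = 2.0 * (1.0 + w2 / (math.pi**2 + w2))
        assert I == pytest.approx(expected, rel=1e-12)

    def test_equatorial_degenerate_band_pair_doubles(self, rings):
        """At mu = pi/2 both Lorentzians coincide: intensity = 2N at the
        band centre."""
        g = rings["110"]
        shape = fd.PeakShape(3.0, math.radians(5), g.q0_nominal, 0.3)
        n = np.array([0.0, 1.0, 0.0])
        Q = g.q0_nominal * np.array([1.0, 0.0, 0.0])  # perpendicular to n
        assert fd.single_fibril_intensity(Q, n, g, shape) == pytest.approx(
            6.0, rel=1e-12
        )

    def test_zero_vector_rejected(self, rings):
        shape = fd.PeakShape(1.0, 0.1, rings["002"].q0_nominal, 0.3)
        with pytest.raises(ValueError):
            fd.single_fibril_intensity(np.zeros(3), np.array([0, 1.0, 0]),
                                       rings["002"], shape)

    def test_brute_force_ring_oracle(self):
        """Analytic intensity equals the dense rotated-ring construction."""
        rng = np.random.default_rng(42)
        for _ in range(8):
            mu = rng.uniform(0, math.pi / 2)
            q0 = rng.uniform(8, 20)
            geom = fd.ReflectionGeometry(mu=mu, q0_nominal=q0)
            shape = fd.PeakShape(
                1.0, rng.uniform(math.radians(2), math.radians(15)), q0, 0.35
            )
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            Q = rng.normal(size=3)
            Q = Q / np.linalg.norm(Q) * rng.uniform(q0 - 0.5, q0 + 0.5)
            fast = fd.single_fibril_intensity(Q, n, geom, shape)
            slow = brute_force_intensity(Q, n, geom, shape)
            assert fast == pytest.approx(slow, rel=1e-3)


class TestArrayIntensity:
    def test_delta_equals_single_fibril(self, rings, beam14):
        g = rings["110"]
        shape = fd.PeakShape(1.0, math.radians(6), g.q0_nominal, 0.3)
        orient = fd.Orientation(0.2, -0.1)
        gm = fd.GammaModel("delta", gamma0=1.0)
        Q = fd.ewald_vector(g.q0_nominal, np.linspace(0, 6, 25), beam14)
        direct = fd.single_fibril_intensity(
            Q, fd.fibre_direction(1.0, orient), g, shape
        )
        assert np.allclose(fd.array_intensity(Q, orient, gm, g, shape), direct)

    def test_narrow_gaussian_converges_to_delta(self, rings, beam14):
        """A wrapped Gaussian with vanishing width reproduces the delta
        branch (gamma0 placed on a quadrature node)."""
        g = rings["110"]
        shape = fd.PeakShape(1.0, math.radians(6), g.q0_nominal, 0.3)
        orient = fd.Orientation(0.1, 0.05)
        n_gamma = 181
        g0 = (90 + 0.5) * math.pi / n_gamma  # node of the midpoint rule
        Q = fd.ewald_vector(g.q0_nominal, np.linspace(0, 6, 25), beam14)
        delta = fd.array_intensity(
            Q, orient, fd.GammaModel("delta", gamma0=g0), g, shape
        )
        narrow = fd.array_intensity(
            Q, orient, fd.GammaModel("gaussian", gamma0=g0, delta_gamma0=1e-4),
            g, shape, n_gamma=n_gamma,
        )
        assert np.allclose(narrow, delta, rtol=1e-6)

    def test_uniform_matches_dense_riemann_sum(self, rings, beam14):
        """Fixed-order quadrature vs a 10x denser uniform gamma grid."""
        g = rings["013"]
        shape = fd.PeakShape(1.0, math.radians(8), g.q0_nominal, 0.3)
        orient = fd.Orientation(0.15, -0.3)
        Q = fd.ewald_vector(g.q0_nominal, np.linspace(0, 6, 40), beam14)
        fast = fd.array_intensity(Q, orient, fd.GammaModel("uniform"), g, shape,
                                  n_gamma=181)
        gammas = (np.arange(1810) + 0.5) * math.pi / 1810
        dense = np.zeros(40)
        for gam in gammas:
            dense += fd.single_fibril_intensity(
                Q, fd.fibre_direction(gam, orient), g, shape
            )
        dense /= len(gammas)
        assert np.allclose(fast, dense, rtol=1e-3)


class TestAzimuthalProfile:
    def test_uniform_untilted_profile_is_flat(self, rings, beam14, chi_grid):
        """A full Bouligand stack normal to the beam gives a uniform ring."""
        for lab in ("002", "110", "013"):
            g = rings[lab]
            shape = fd.PeakShape(1.0, math.radians(5), g.q0_nominal, 0.3)
            prof = fd.azimuthal_profile(
                g, shape, fd.Orientation(0, 0), fd.GammaModel("uniform"),
                beam14, chi_grid,
            )
            cv = prof.intensity.std() / prof.intensity.mean()
            assert cv < 1e-6

    def test_axial_two_maxima_at_90_and_270(self, rings, beam14):
        """Untilted vertical fibril: (002) peaks exactly at pi/2 and 3pi/2."""
        g = rings["002"]
        shape = fd.PeakShape(1.0, math.radians(5), g.q0_nominal, 0.3)
        chi = np.radians(np.arange(0, 360, 0.1))
        prof = fd.azimuthal_profile(
            g, shape, fd.Orientation(0, 0),
            fd.GammaModel("delta", gamma0=math.pi / 2), beam14, chi,
        )
        s = fd.summarize_profile(prof)
        assert len(s.positions) == 2
        assert np.degrees(s.positions) == pytest.approx([90.0, 270.0], abs=0.1)

    def test_mirror_symmetry_untilted(self, rings, beam14):
        """At zero tilt a vertical fibre profile obeys I(chi) = I(pi - chi)
        = I(chi + pi) to 1e-3 relative (fibre symmetry, flat-Ewald limit)."""
        chi = np.radians(np.arange(0, 360, 0.5))
        nb = len(chi)
        for lab in ("002", "110", "013"):
            g = fd.ring_geometry(fd.ALPHA_CHITIN_CELL, fd.CHITIN_REFLECTIONS[lab])
            shape = fd.PeakShape(1.0, math.radians(6), g.q0_nominal, 0.3)
            prof = fd.azimuthal_profile(
                g, shape, fd.Orientation(0, 0),
                fd.GammaModel("delta", gamma0=math.pi / 2), beam14, chi,
            )
            I = prof.intensity
            scale = I.max()
            assert np.allclose(I, np.roll(I[::-1], nb // 2 + 1), atol=1e-3 * scale)
            assert np.allclose(I, np.roll(I, nb // 2), atol=1e-3 * scale)

    def test_axial_reflection_vanishes_when_fibre_tips_into_beam(
        self, rings, beam14, chi_grid
    ):
        """(0kl) rings no longer intersect the Ewald sphere once the fibre
        tilts far enough toward the beam axis."""
        g = rings["002"]
        # narrow band: the Lorentzian tails set the visibility floor
        shape = fd.PeakShape(1.0, math.radians(3), g.q0_nominal, 0.3)
        gm = fd.GammaModel("delta", gamma0=math.pi / 2)
        untilted = fd.azimuthal_profile(
            g, shape, fd.Orientation(0, 0), gm, beam14, chi_grid
        )
        tipped = fd.azimuthal_profile(
            g, shape, fd.Orientation(math.radians(85), 0), gm, beam14, chi_grid
        )
        assert tipped.intensity.max() < 0.01 * untilted.intensity.max()

    def test_apparent_broadening_under_spread_and_tilt(self, rings, beam14):
        """(110) azimuthal FWHM grows monotonically both with the in-plane
        spread at fixed tilt and with out-of-plane tilt at fixed spread —
        the two are indistinguishable in a single 2D measure."""
        g = rings["110"]
        shape = fd.PeakShape(1.0, math.radians(5), g.q0_nominal, 0.3)
        chi = np.radians(np.arange(0, 360, 0.1))

        def fwhm(orient, gm):
            prof = fd.azimuthal_profile(g, shape, orient, gm, beam14, chi)
            s = fd.summarize_profile(prof)
            return float(np.nanmean(s.fwhm))

        spread = [
            fwhm(fd.Orientation(0, 0),
                 fd.GammaModel("gaussian", gamma0=math.pi / 2,
                               delta_gamma0=math.radians(d)))
            for d in (1, 5, 10, 15)
        ]
        assert np.all(np.diff(spread) > 0)
        tilt = [
            fwhm(fd.Orientation(math.radians(a), 0),
                 fd.GammaModel("delta", gamma0=math.pi / 2))
            for a in (0, 10, 20, 30)
        ]
        assert np.all(np.diff(tilt) > 0)


class TestRenderPattern:
    def test_zero_amplitude_gives_zero_image(self, small_detector, rings, beam14):
        g = rings["110"]
        shape = fd.PeakShape(0.0, math.radians(5), g.q0_nominal, 0.3)
        img = fd.render_pattern(
            small_detector, [g], [shape], fd.Orientation(0, 0),
            fd.GammaModel("uniform"), beam14, n_gamma=61,
        )
        assert np.all(img.counts == 0)

    def test_untilted_uniform_ring_is_rotationally_uniform(
        self, small_detector, rings, beam14
    ):
        g = rings["110"]
        shape = fd.PeakShape(100.0, math.radians(5), g.q0_nominal, 0.3)
        img = fd.render_pattern(
            small_detector, [g], [shape], fd.Orientation(0, 0),
            fd.GammaModel("uniform"), beam14, n_gamma=121,
        )
        q0 = g.q0_nominal
        prof = fd.azimuthal_integrate(
            img, small_detector, (q0 - 0.15, q0 + 0.15), n_chi_bins=90
        )
        v = prof.intensity[prof.valid]
        assert v.std() / v.mean() < 0.01

    def test_gap_pixels_masked_and_zero(self, gapped_detector, rings, beam14):
        g = rings["110"]
        shape = fd.PeakShape(10.0, math.radians(5), g.q0_nominal, 0.3)
        img = fd.render_pattern(
            gapped_detector, [g], [shape], fd.Orientation(0, 0),
            fd.GammaModel("delta", gamma0=1.0), beam14,
        )
        assert not img.mask[48, :].any()
        assert np.all(img.counts[48, :] == 0)
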