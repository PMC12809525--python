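import math

import numpy as np
import pytest

import fibrediff as fd
from fibrediff.estimators import TiltDecomposition, compose_orientation
from fibrediff.fitting import (
    JointAzimuthalModel,
    JointFitConfig,
    export_orientation_glyphs,
    fit_scan,
    initial_guess,
)


def make_l1_profiles(orient, chi, beam, chitin_shapes, peak_counts=1000.0,
                     rng=None, n_gamma=121):
    geoms, shapes, labels = chitin_shapes
    profiles = {}
    for lab, g, s in zip(labels, geoms, shapes):
        m = fd.azimuthal_profile(g, s, orient, fd.GammaModel("uniform"),
                                 beam, chi, n_gamma=n_gamma)
        scale = peak_counts / m.intensity.max()
        counts = m.intensity * scale
        if rng is not None:
            counts = rng.poisson(counts).astype(float)
        profiles[lab] = fd.AzimuthalProfile(chi, counts)
    return profiles


def make_l3_profiles(n_true, chi, beam, chitin_shapes, scale=3.0, rng=None):
    geoms, shapes, labels = chitin_shapes
    profiles = {}
    for lab, g, s in zip(labels, geoms, shapes):
        Q = fd.ewald_vector(g.q0_nominal, chi, beam)
        I = fd.single_fibril_intensity(
            Q, n_true, g, fd.PeakShape(s.amplitude, s.w_mu, g.q0_nominal, 1.0)
        ) * scale
        if rng is not None:
            I = rng.poisson(np.maximum(I, 0)).astype(float)
        profiles[lab] = fd.AzimuthalProfile(chi, I)
    return profiles


@pytest.fixture(scope="module")
def ring_geoms(chitin_shapes):
    geoms, _, labels = chitin_shapes
    return dict(zip(labels, geoms))


class TestInitialGuess:
    def test_flat_profiles_seed_zero_tilt(self, ring_geoms, beam14, chi_grid):
        profiles = {
            lab: fd.AzimuthalProfile(chi_grid, np.full(len(chi_grid), 50.0))
            for lab in ring_geoms
        }
        seed = initial_guess(profiles, ring_geoms, beam14,
                             JointFitConfig(mode="L1_uniform"))
        assert seed["alpha"] == 0.0 and seed["beta"] == 0.0

    def test_l3_seed_close_to_truth(self, ring_geoms, beam14, chi_grid,
                                    chitin_shapes):
        """Noiseless single-fibre profiles seed the in-plane angle within
        3 degrees of truth."""
        g0 = math.radians(70.0)
        n = compose_orientation(TiltDecomposition(g0 - math.pi / 2,
                                                  math.radians(5)))
        profiles = make_l3_profiles(n, chi_grid, beam14, chitin_shapes)
        seed = initial_guess(profiles, ring_geoms, beam14,
                             JointFitConfig(mode="L3_delta"))
        assert abs(math.degrees(seed["gamma0"]) - 70.0) < 3.0

    def test_seed_without_axial_reflections(self, ring_geoms, beam14,
                                            chi_grid, chitin_shapes):
        """(0kl) profiles absent: the equatorial profile alone still seeds."""
        n = compose_orientation(TiltDecomposition(0.2, 0.1))
        profiles = make_l3_profiles(n, chi_grid, beam14, chitin_shapes)
        only110 = {"110": profiles["110"]}
        seed = initial_guess(only110, ring_geoms, beam14,
                             JointFitConfig(mode="L3_delta"))
        assert "gamma0" in seed and "w_mu_110" in seed


class TestJointFitL1:
    def test_zero_tilt_identifiability_guard(self, ring_geoms, beam14,
                                             chi_grid, chitin_shapes):
        """At exactly zero tilt the uniform-stack profiles are flat: the fit
        must report near-zero tilt with large relative uncertainty, not
        spuriously precise angles."""
        profiles = make_l1_profiles(fd.Orientation(0, 0), chi_grid, beam14,
                                    chitin_shapes)
        model = JointAzimuthalModel(profiles, ring_geoms, beam14,
                                    JointFitConfig(mode="L1_uniform",
                                                   n_gamma=121))
        res = model.fit()
        assert abs(math.degrees(res.params["alpha"])) < 0.5
        assert abs(math.degrees(res.params["beta"])) < 0.5
        # uncertainty dwarfs the (near-zero) estimate
        assert res.stderr["alpha"] > 5 * abs(res.params["alpha"]) or \
            res.stderr["alpha"] > math.radians(0.5)

    def test_recovers_reference_tilt_pair(self, ring_geoms, beam14, chi_grid,
                                          chitin_shapes):
        """Tilts of a few to ~25 degrees (the regime seen in real cuticle
        samples) recover within 1 deg in alpha, 2 deg in beta under Poisson
        noise at ~1e3 peak counts."""
        truth = fd.Orientation(math.radians(-2.0), math.radians(24.0))
        for seed in range(3):
            rng = np.random.default_rng(seed)
            profiles = make_l1_profiles(truth, chi_grid, beam14,
                                        chitin_shapes, rng=rng)
            model = JointAzimuthalModel(
                profiles, ring_geoms, beam14,
                JointFitConfig(mode="L1_uniform", n_gamma=121),
            )
            res = model.fit()
            assert abs(math.degrees(res.params["alpha"]) - (-2.0)) < 1.0
            assert abs(math.degrees(res.params["beta"]) - 24.0) < 2.0

    def test_summary_lists_parameters(self, ring_geoms, beam14, chi_grid,
                                      chitin_shapes):
        profiles = make_l1_profiles(fd.Orientation(0.1, 0.1), chi_grid,
                                    beam14, chitin_shapes)
        res = JointAzimuthalModel(
            profiles, ring_geoms, beam14,
            JointFitConfig(mode="L1_uniform", n_gamma=61),
        ).fit()
        text = res.summary()
        for token in ("alpha", "beta", "w_mu_110", "residual norm"):
            assert token in text
        rec = res.to_record()
        assert rec["schema_version"] == 1
        assert set(rec["reflections_used"]) == {"002", "110", "013"}


class TestJointFitL3:
    def test_visibility_selection_and_110_only_fit(self, ring_geoms, beam14,
                                                   chi_grid, chitin_shapes):
        """Fibre near the detector plane uses all three reflections; fibre
        tipped toward the beam loses the (0kl) rings but the (110)-only fit
        still converges to the right axis."""
        rng = np.random.default_rng(3)
        near_plane = compose_orientation(
            TiltDecomposition(math.radians(-20), math.radians(8))
        )
        m1 = JointAzimuthalModel(
            make_l3_profiles(near_plane, chi_grid, beam14, chitin_shapes,
                             rng=rng),
            ring_geoms, beam14, JointFitConfig(mode="L3_delta"),
        )
        assert set(m1.reflections_used) == {"002", "110", "013"}

        toward_beam = compose_orientation(
            TiltDecomposition(math.radians(-10), math.radians(65))
        )
        m2 = JointAzimuthalModel(
            make_l3_profiles(toward_beam, chi_grid, beam14, chitin_shapes,
                             rng=rng),
            ring_geoms, beam14, JointFitConfig(mode="L3_delta"),
        )
        assert m2.reflections_used == ["110"]
        res = m2.fit()
        err = math.degrees(
            math.acos(min(1.0, abs(float(toward_beam @ res.fibre_axis()))))
        )
        assert err < 2.0

    def test_multi_reflection_fit_beats_equatorial_only(
        self, ring_geoms, beam14, chi_grid, chitin_shapes
    ):
        """Where the (0kl) rings are visible, the three-reflection joint fit
        has lower orientation error than a (110)-only fit."""
        rng = np.random.default_rng(7)
        errs3, errs1 = [], []
        for ap_deg in (2, 5, 8, 12):
            n_true = compose_orientation(
                TiltDecomposition(math.radians(10), math.radians(ap_deg))
            )
            profiles = make_l3_profiles(n_true, chi_grid, beam14,
                                        chitin_shapes, scale=0.6, rng=rng)
            for use, acc in ((None, errs3), (["110"], errs1)):
                p = profiles if use is None else {k: profiles[k] for k in use}
                res = JointAzimuthalModel(
                    p, ring_geoms, beam14, JointFitConfig(mode="L3_delta")
                ).fit()
                acc.append(math.degrees(math.acos(min(
                    1.0, abs(float(n_true @ res.fibre_axis()))))))
        assert np.sqrt(np.mean(np.square(errs3))) < \
            np.sqrt(np.mean(np.square(errs1)))


@pytest.fixture(scope="module")
def small_scan(small_detector):
    stack = fd.BouligandStack(
        n_lamellae=1, lamella_thicknesses_um=(60.0,),
        rotation_pitch_deg_per_um=3.0,
        stack_tilt=(math.radians(6), 0.0),
        gamma_start=math.radians(10),
    )
    frames, truth = fd.simulate_scan(
        stack, small_detector, step_um=10.0,
        noise=fd.NoiseModel(exposure_scale=3.0, poisson=True, seed=11),
    )
    return frames, truth, small_detector


class TestFitScan:

    def test_single_frame_scan_matches_direct_fit(self, small_scan, cell):
        frames, truth, det = small_scan
        cfg = JointFitConfig(mode="L3_delta")
        scan = fit_scan(frames[:1], det, cell, cfg, scan_shape=(1, 1))
        direct_profiles = {
            lab: fd.azimuthal_integrate(frames[0], det, spec.radial_band)
            for lab, spec in fd.CHITIN_REFLECTIONS.items()
        }
        geoms = {lab: fd.ring_geometry(cell, spec)
                 for lab, spec in fd.CHITIN_REFLECTIONS.items()}
        direct = JointAzimuthalModel(
            direct_profiles, geoms, fd.BeamGeometry(det.wavelength_nm), cfg
        ).fit()
        assert scan.maps["gamma0"][0, 0] == pytest.approx(
            direct.params["gamma0"], abs=1e-6
        )
        assert scan.fit_results[0].params == pytest.approx(direct.params)

    def test_spiral_pitch_recovered(self, small_scan, cell):
        """The programmed Bouligand rotation rate is recovered from the
        fitted in-plane angles within 5%."""
        frames, truth, det = small_scan
        scan = fit_scan(frames, det, cell, JointFitConfig(mode="L3_delta"),
                        scan_shape=(len(frames), 1), step_um=(7.0, 10.0))
        assert scan.ok.all()
        g = scan.maps["gamma0"].ravel().copy()
        for i in range(1, len(g)):  # unwrap the pi-periodic angle
            while g[i] - g[i - 1] > math.pi / 2:
                g[i] -= math.pi
            while g[i] - g[i - 1] < -math.pi / 2:
                g[i] += math.pi
        z = truth["z_um"].to_numpy()
        slope = math.degrees(np.polyfit(z, g, 1)[0])
        assert slope == pytest.approx(3.0, rel=0.05)

    def test_dead_frame_flagged_in_isolation(self, small_scan, cell):
        frames, truth, det = small_scan
        dead = fd.DetectorImage(np.zeros(det.shape), det.gap_mask())
        seq = [frames[0], dead, frames[2]]
        scan = fit_scan(seq, det, cell, JointFitConfig(mode="L3_delta"),
                        scan_shape=(3, 1))
        assert not scan.ok[1, 0]
        assert scan.ok[0, 0] and scan.ok[2, 0]
        assert np.isnan(scan.maps["gamma0"][1, 0])

    def test_glyph_export(self, small_scan, cell):
        frames, truth, det = small_scan
        scan = fit_scan(frames[:3], det, cell, JointFitConfig(mode="L3_delta"),
                        scan_shape=(3, 1))
        g1 = export_orientation_glyphs(scan, elongation_scale=math.radians(5))
        g2 = export_orientation_glyphs(scan, elongation_scale=math.radians(10))
        assert len(g1) == 3
        norms = np.linalg.norm(g1[["nx", "ny", "nz"]].to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)
        # elongation is inverse in w_mu, linear in the scale
        assert np.allclose(g2["elongation"], 2 * g1["elongation"])
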