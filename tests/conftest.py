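import math

import numpy as np
import pytest

import fibrediff as fd


@pytest.fixture(scope="session")
def beam14():
    """14 keV beam (microfocus conditions)."""
    return fd.BeamGeometry.from_energy_kev(14.0)


@pytest.fixture(scope="session")
def cell():
    return fd.ALPHA_CHITIN_CELL


@pytest.fixture(scope="session")
def rings(cell):
    """ReflectionGeometry for the three chitin reflections, keyed by label."""
    return {
        lab: fd.ring_geometry(cell, spec)
        for lab, spec in fd.CHITIN_REFLECTIONS.items()
    }


@pytest.fixture(scope="session")
def chitin_shapes():
    """(geoms, shapes, labels) with realistic amplitudes and widths."""
    return fd.default_shapes()


@pytest.fixture(scope="session")
def chi_grid():
    """1-degree bin centres over the full azimuthal range."""
    return np.radians(np.arange(0.5, 360.0, 1.0))


@pytest.fixture(scope="session")
def small_detector(beam14):
    """Coarse gapless detector covering the chitin q-range, fast to render."""
    return fd.DetectorGeometry(
        distance_mm=296.0,
        pixel_size_um=600.0,
        beam_centre=(149.5, 149.5),
        n_pixels=(300, 300),
        wavelength_nm=beam14.wavelength_nm,
    )


@pytest.fixture(scope="session")
def gapped_detector(beam14):
    """Same coverage with one horizontal module gap crossing the rings."""
    return fd.DetectorGeometry(
        distance_mm=296.0,
        pixel_size_um=600.0,
        beam_centre=(149.5, 149.5),
        n_pixels=(300, 300),
        gaps=(fd.GapStrip("y", 45, 14),),
        wavelength_nm=beam14.wavelength_nm,
    )


def brute_force_intensity(Qvec, n, geom, shape, npts=100_000):
    """Independent geometric oracle for the single-fibril intensity.

    Constructs the two reflection rings (polar angles mu and pi - mu about
    the fibre axis) as dense 3D point sets, takes the minimum arc distance
    from the query direction to each ring as the Lorentzian argument, and
    multiplies by the radial Gaussian.
    """
    n = np.asarray(n, float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    t = np.linspace(0, 2 * np.pi, npts, endpoint=False)
    qmag = np.linalg.norm(Qvec)
    qhat = np.asarray(Qvec, float) / qmag
    w2 = shape.w_mu**2
    band = 0.0
    for mu in (geom.mu, math.pi - geom.mu):
        ring = np.cos(mu) * n[None, :] + np.sin(mu) * (
            np.cos(t)[:, None] * e1 + np.sin(t)[:, None] * e2
        )
        d = np.arccos(np.clip(ring @ qhat, -1.0, 1.0)).min()
        band += w2 / (d * d + w2)
    radial = math.exp(-((qmag - shape.q0) ** 2) / (2 * shape.dq**2))
    return shape.amplitude * band * radial
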