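"""Reciprocal-space forward model for fibre-symmetric diffraction.

The intensity of an (hkl) ring from a single fibril is the product of two
orthogonal peak profiles: a band profile on the unit sphere (two symmetric
Lorentzian bands in the latitude angle phi = arcsin(Qhat . n), centred at
+-(pi/2 - mu), realizing the rings at mu and pi - mu around the +-c fibre
directions) and a radial Gaussian in |Q| centred at q0 with width dq:

    I(Q) = N * [ L(phi - (pi/2 - mu); w_mu) + L(phi + (pi/2 - mu); w_mu) ]
             * exp( -(|Q| - q0)^2 / (2 dq^2) ),

with L(x; w) = w^2 / (x^2 + w^2) a unit-height Lorentzian.  A planar array
of fibrils integrates this over the in-plane angle gamma with a density
w(gamma) of period pi (fibres are axes): uniform 1/pi for a full Bouligand
stack, a wrapped Gaussian for a partial spread, or a Dirac delta for a
single fibre direction.

Detector intensity uses the exact Ewald condition: at azimuth chi and
scattering-vector magnitude q the lab-frame vector is

    Q = ( q cos(theta) cos(chi), q cos(theta) sin(chi), q sin(theta) ),

with sin(theta) = q lambda / (4 pi); no small-angle flattening is applied,
since the Ewald curvature is what displaces equatorial peak separations
from 180 degrees.  The lab frame is right-handed with x horizontal and y
vertical on the detector and the beam propagating along -z, so
Q = k_out - k_in has a positive z component and a positive alpha tilt
(fibre top tipping toward +z, away from the detector) strengthens the
upper (chi = 90 deg) axial peak — the standard sense in fibre-diffraction
work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detector import DetectorGeometry, DetectorImage, polar_map
from .lattice import ReflectionGeometry
from .profiles import AzimuthalProfile

__all__ = [
    "BeamGeometry",
    "PeakShape",
    "Orientation",
    "GammaModel",
    "ewald_vector",
    "fibre_direction",
    "rot_x",
    "rot_y",
    "rot_z",
    "single_fibril_intensity",
    "array_intensity",
    "azimuthal_profile",
    "render_pattern",
    "DEFAULT_N_GAMMA",
]

DEFAULT_N_GAMMA = 181


@dataclass(frozen=True)
class BeamGeometry:
    """Monochromatic beam along +z; wavelength in nm."""

    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    @classmethod
    def from_energy_kev(cls, energy_kev: float) -> "BeamGeometry":
        """lambda(nm) = 1.2398 / E(keV)."""
        return cls(wavelength_nm=1.2398 / energy_kev)

    @property
    def k(self) -> float:
        """Wavenumber 2 pi / lambda in 1/nm."""
        return 2.0 * math.pi / self.wavelength_nm


@dataclass(frozen=True)
class PeakShape:
    """Free intensity parameters of one reflection.

    amplitude absorbs structure factor, exposure and detector response;
    w_mu (rad) is the Lorentzian angular band width on the unit sphere;
    q0 and dq (1/nm) are the radial Gaussian centre and width.
    """

    amplitude: float
    w_mu: float
    q0: float
    dq: float

    def __post_init__(self) -> None:
        if self.w_mu <= 0 or self.dq <= 0 or self.amplitude < 0:
            raise ValueError("require w_mu > 0, dq > 0, amplitude >= 0")


def _wrap_pi(x: float) -> float:
    """Wrap to (-pi, pi]."""
    y = math.remainder(x, 2.0 * math.pi)
    return y if y != -math.pi else math.pi


@dataclass(frozen=True)
class Orientation:
    """Out-of-plane tilts: alpha about lab x (rotating +y toward +z), beta
    about lab y (rotating +z toward +x).  Stored wrapped to (-pi, pi]."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _wrap_pi(self.alpha))
        object.__setattr__(self, "beta", _wrap_pi(self.beta))


@dataclass(frozen=True)
class GammaModel:
    """In-plane fibre-angle distribution w(gamma), period pi.

    kind='uniform': w = 1/pi on [0, pi) (full Bouligand stack).
    kind='gaussian': wrapped normal, centre gamma0, width delta_gamma0.
    kind='delta': all mass at gamma0 (single fibre direction).
    """

    kind: str
    gamma0: float = 0.0
    delta_gamma0: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian", "delta"):
            raise ValueError("kind must be 'uniform', 'gaussian' or 'delta'")
        if self.kind == "gaussian":
            if self.delta_gamma0 is None or self.delta_gamma0 <= 0:
                raise ValueError("gaussian GammaModel requires delta_gamma0 > 0")

    def density(self, gamma: np.ndarray) -> np.ndarray:
        """Normalized density on [0, pi); not defined for kind='delta'."""
        gamma = np.asarray(gamma, dtype=float)
        if self.kind == "uniform":
            return np.full(gamma.shape, 1.0 / math.pi)
        if self.kind == "delta":
            raise ValueError("delta distribution has no density")
        s = self.delta_gamma0
        out = np.zeros_like(gamma)
        # wrapped normal: sum of periodic images (period pi)
        for m in range(-4, 5):
            out += np.exp(-((gamma - self.gamma0 - m * math.pi) ** 2) / (2 * s * s))
        return out / (math.sqrt(2 * math.pi) * s)


def rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def ewald_vector(q, chi, beam: BeamGeometry) -> np.ndarray:
    """Lab-frame scattering vector(s) on the Ewald sphere, shape (..., 3).

    Broadcasts over q and chi.  Requires 0 <= q < 2k (backscattering limit).
    """
    q = np.asarray(q, dtype=float)
    chi = np.asarray(chi, dtype=float)
    if np.any(q < 0) or np.any(q >= 2.0 * beam.k):
        raise ValueError("require 0 <= q < 2k for a diffraction solution")
    q_, chi_ = np.broadcast_arrays(q, chi)
    sin_t = q_ * beam.wavelength_nm / (4.0 * math.pi)
    cos_t = np.sqrt(1.0 - sin_t**2)
    return np.stack(
        [
            q_ * cos_t * np.cos(chi_),
            q_ * cos_t * np.sin(chi_),
            q_ * sin_t,
        ],
        axis=-1,
    )


def fibre_direction(gamma, orient: Orientation) -> np.ndarray:
    """Unit fibre-axis direction n = R_x(alpha) R_y(beta) (cos g, sin g, 0).

    Broadcasts over gamma; returns shape (..., 3).
    """
    gamma = np.asarray(gamma, dtype=float)
    v = np.stack(
        [np.cos(gamma), np.sin(gamma), np.zeros_like(gamma)], axis=-1
    )
    R = rot_x(orient.alpha) @ rot_y(orient.beta)
    return v @ R.T


def single_fibril_intensity(
    Qvec, n, geom: ReflectionGeometry, shape: PeakShape
) -> np.ndarray:
    """Reciprocal-space intensity of one fibril at lab vector(s) Qvec.

    Qvec has shape (..., 3); n is a broadcast-compatible unit vector (or
    stack of unit vectors).  Zero-length Q is a domain error.
    """
    Qvec = np.asarray(Qvec, dtype=float)
    n = np.asarray(n, dtype=float)
    qmag = np.linalg.norm(Qvec, axis=-1)
    if np.any(qmag == 0.0):
        raise ValueError("zero-length scattering vector")
    sin_phi = np.clip(np.sum(Qvec * n, axis=-1) / qmag, -1.0, 1.0)
    phi = np.arcsin(sin_phi)
    centre = 0.5 * math.pi - geom.mu
    w2 = shape.w_mu**2
    band = w2 / ((phi - centre) ** 2 + w2) + w2 / ((phi + centre) ** 2 + w2)
    radial = np.exp(-((qmag - shape.q0) ** 2) / (2.0 * shape.dq**2))
    return shape.amplitude * band * radial


def _gamma_nodes(n_gamma: int) -> np.ndarray:
    """Midpoint nodes on [0, pi): optimal for pi-periodic integrands."""
    return (np.arange(n_gamma) + 0.5) * math.pi / n_gamma


def array_intensity(
    Qvec,
    orient: Orientation,
    gm: GammaModel,
    geom: ReflectionGeometry,
    shape: PeakShape,
    n_gamma: int = DEFAULT_N_GAMMA,
) -> np.ndarray:
    """Planar-array intensity: integral of the single-fibril intensity over
    the in-plane angle gamma weighted by w(gamma).

    The delta kind bypasses quadrature; uniform and gaussian kinds use a
    fixed-order midpoint rule on [0, pi) (spectrally accurate for the
    pi-periodic integrand).  Gaussian weights are renormalized to sum to 1
    so narrow distributions do not lose mass to undersampling.
    """
    if gm.kind == "delta":
        n = fibre_direction(gm.gamma0, orient)
        return single_fibril_intensity(Qvec, n, geom, shape)
    nodes = _gamma_nodes(n_gamma)
    if gm.kind == "uniform":
        weights = np.full(n_gamma, 1.0 / n_gamma)
    else:
        w = gm.density(nodes)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("non-normalizable gamma distribution")
        weights = w / total
    Qvec = np.asarray(Qvec, dtype=float)
    lead_shape = Qvec.shape[:-1]
    Q = Qvec.reshape(-1, 3)
    qmag = np.linalg.norm(Q, axis=-1)
    if np.any(qmag == 0.0):
        raise ValueError("zero-length scattering vector")
    N = fibre_direction(nodes, orient)  # (G, 3)
    centre = 0.5 * math.pi - geom.mu
    w2 = shape.w_mu**2
    radial = shape.amplitude * np.exp(
        -((qmag - shape.q0) ** 2) / (2.0 * shape.dq**2)
    )
    out = np.empty(Q.shape[0], dtype=float)
    # chunk the pixel axis to bound the (pixels x gamma-nodes) temporary
    chunk = max(1, 8_000_000 // n_gamma)
    for i in range(0, Q.shape[0], chunk):
        sl = slice(i, i + chunk)
        sin_phi = np.clip((Q[sl] @ N.T) / qmag[sl, None], -1.0, 1.0)
        phi = np.arcsin(sin_phi)
        band = w2 / ((phi - centre) ** 2 + w2) + w2 / ((phi + centre) ** 2 + w2)
        out[sl] = (band @ weights) * radial[sl]
    return out.reshape(lead_shape)


def azimuthal_profile(
    geom: ReflectionGeometry,
    shape: PeakShape,
    orient: Orientation,
    gm: GammaModel,
    beam: BeamGeometry,
    chi_grid: np.ndarray,
    n_gamma: int = DEFAULT_N_GAMMA,
) -> AzimuthalProfile:
    """Model azimuthal profile I(chi) at fixed q = q0 on the Ewald sphere.

    The radial Gaussian equals 1 at q = q0 by construction, so the profile
    isolates the angular band structure.
    """
    chi_grid = np.asarray(chi_grid, dtype=float)
    Q = ewald_vector(shape.q0, chi_grid, beam)
    I = array_intensity(Q, orient, gm, geom, shape, n_gamma=n_gamma)
    return AzimuthalProfile(chi=chi_grid, intensity=I)


def render_pattern(
    detector: DetectorGeometry,
    reflections: list[ReflectionGeometry],
    shapes: list[PeakShape],
    orient: Orientation,
    gm: GammaModel,
    beam: BeamGeometry | None = None,
    n_gamma: int = DEFAULT_N_GAMMA,
) -> DetectorImage:
    """Render a 2D pattern: per-pixel sum of array intensities over reflections.

    Gap pixels are zeroed and masked; pixels beyond the q < 2k Ewald limit
    are excluded via the mask.
    """
    if len(reflections) != len(shapes):
        raise ValueError("reflections and shapes must have equal length")
    if beam is None:
        beam = BeamGeometry(detector.wavelength_nm)
    q, chi = polar_map(detector)
    mask = detector.gap_mask() & (q < 2.0 * beam.k)
    sin_t = q * beam.wavelength_nm / (4.0 * math.pi)
    sin_t = np.clip(sin_t, 0.0, 1.0)
    cos_t = np.sqrt(1.0 - sin_t**2)
    Q = np.stack(
        [q * cos_t * np.cos(chi), q * cos_t * np.sin(chi), q * sin_t], axis=-1
    )
    counts = np.zeros(q.shape, dtype=float)
    # beam-centre pixel has |Q| = 0; evaluate off-centre pixels only
    ok = np.linalg.norm(Q, axis=-1) > 0
    for geom, shape in zip(reflections, shapes):
        counts[ok] += array_intensity(Q[ok], orient, gm, geom, shape, n_gamma=n_gamma)
    counts[~mask] = 0.0
    return DetectorImage(counts=counts, mask=mask)
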