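"""Reduction of 2D detector frames to azimuthal and radial profiles.

Implements the standard scanning-WAXD reduction chain: per-pixel (q, chi)
mapping for a flat detector normal to the beam, azimuthal regrouping over a
radial band, ring background subtraction (the per-azimuth mean of two thin
rings flanking the reflection), radial regrouping, and simultaneous
multi-Gaussian fitting of overlapping radial peaks with bounded centres.

Detector module gaps are handled by masking only: azimuthal bins whose
valid-pixel fraction falls below 50% are flagged invalid and never
interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .detector import DetectorGeometry, DetectorImage, polar_map
from .lattice import ReflectionSpec, UnitCell, d_spacing, ring_geometry
from .profiles import AzimuthalProfile, RadialProfile

__all__ = [
    "azimuthal_integrate",
    "ring_background_subtract",
    "radial_integrate",
    "fit_radial_peaks",
    "RadialFitResult",
    "read_tiff",
    "write_tiff",
    "read_h5_stack",
    "write_h5_stack",
]

MIN_VALID_FRACTION = 0.5


def _band_profile(
    image: DetectorImage,
    q: np.ndarray,
    chi: np.ndarray,
    band: tuple[float, float],
    n_chi_bins: int,
) -> AzimuthalProfile:
    """Mean counts of valid pixels per chi bin within a radial band."""
    q_lo, q_hi = band
    in_band = (q >= q_lo) & (q < q_hi)
    if not in_band.any():
        raise ValueError(f"radial band {band} contains no pixels")
    edges = np.linspace(0.0, 2.0 * math.pi, n_chi_bins + 1)
    idx = np.clip(np.digitize(chi[in_band], edges) - 1, 0, n_chi_bins - 1)
    ok = image.mask[in_band]
    counts = image.counts[in_band]
    n_total = np.bincount(idx, minlength=n_chi_bins)
    n_valid = np.bincount(idx[ok], minlength=n_chi_bins)
    sums = np.bincount(idx[ok], weights=counts[ok], minlength=n_chi_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), 0.0)
    valid = (n_total > 0) & (n_valid >= MIN_VALID_FRACTION * n_total)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return AzimuthalProfile(chi=centres, intensity=mean, valid=valid)


def azimuthal_integrate(
    image: DetectorImage,
    geometry: DetectorGeometry,
    radial_band: tuple[float, float],
    n_chi_bins: int = 360,
) -> AzimuthalProfile:
    """Azimuthal profile I(chi): mean valid-pixel counts per chi bin in the band.

    Bins whose valid-pixel fraction is below 50% (module gaps) are masked.
    """
    q, chi = polar_map(geometry)
    if radial_band[0] >= radial_band[1]:
        raise ValueError("radial band must satisfy q_min < q_max")
    if radial_band[0] > q.max():
        raise ValueError("radial band beyond detector q-range")
    return _band_profile(image, q, chi, radial_band, n_chi_bins)


def ring_background_subtract(
    image: DetectorImage,
    geometry: DetectorGeometry,
    band: tuple[float, float],
    inner_only: bool = False,
    n_chi_bins: int = 360,
    ring_width: float = 0.2,
    guard: float = 0.1,
    clip_negative: bool = True,
) -> AzimuthalProfile:
    """Background-corrected azimuthal profile of a reflection band.

    The background is the per-chi mean of two rings of width ``ring_width``
    (1/nm) placed ``guard`` below and above the band (inner ring only when
    ``inner_only`` — used when an overlapping neighbour leaves no clean
    outer ring).  Negative bins are clipped at zero by default; the clipped
    fraction is stored as ``profile.clip_fraction``.
    """
    q, chi = polar_map(geometry)
    inner = (band[0] - guard - ring_width, band[0] - guard)
    outer = (band[1] + guard, band[1] + guard + ring_width)
    if inner[0] <= 0:
        raise ValueError("inner background ring extends below q = 0")
    if inner[1] > band[0] or (not inner_only and outer[0] < band[1]):
        raise ValueError("background ring overlaps the reflection band")
    signal = _band_profile(image, q, chi, band, n_chi_bins)
    bg_in = _band_profile(image, q, chi, inner, n_chi_bins)
    if inner_only:
        background = bg_in.intensity
        bg_valid = bg_in.valid
    else:
        bg_out = _band_profile(image, q, chi, outer, n_chi_bins)
        background = 0.5 * (bg_in.intensity + bg_out.intensity)
        bg_valid = bg_in.valid & bg_out.valid
    corrected = signal.intensity - background
    valid = signal.valid & bg_valid
    clip_fraction = 0.0
    if clip_negative:
        neg = (corrected < 0) & valid
        clip_fraction = float(neg.sum()) / max(int(valid.sum()), 1)
        corrected = np.where(neg, 0.0, corrected)
    out = AzimuthalProfile(chi=signal.chi, intensity=corrected, valid=valid)
    out.clip_fraction = clip_fraction
    return out


def radial_integrate(
    image: DetectorImage,
    geometry: DetectorGeometry,
    q_range: tuple[float, float] = (4.1, 25.7),
    bin_width: float = 0.05,
) -> RadialProfile:
    """Azimuthally averaged I(q) over valid pixels on uniform q bins."""
    q, _ = polar_map(geometry)
    lo, hi = q_range
    if lo >= hi:
        raise ValueError("q_range must satisfy q_min < q_max")
    if lo > q.max():
        raise ValueError("q_range beyond detector coverage")
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = np.linspace(lo, hi, n_bins + 1)
    sel = (q >= lo) & (q < hi) & image.mask
    idx = np.clip(np.digitize(q[sel], edges) - 1, 0, n_bins - 1)
    n_valid = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=image.counts[sel], minlength=n_bins)
    mean = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), 0.0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(q=centres, intensity=mean, valid=n_valid > 0)


@dataclass
class RadialFitResult:
    """Multi-Gaussian radial fit of one primary reflection.

    q_centre/sigma in 1/nm, area in counts/nm; d_spacing = 2pi/q_centre.
    ``at_bound`` flags a centre pinned at its +-2% window edge;
    ``converged`` is False for a failed minimization (values are then the
    best available, flagged rather than raised).
    """

    label: str
    q_centre: float
    sigma: float
    area: float
    d_spacing: float
    converged: bool
    at_bound: bool
    redchi: float = math.nan
    components: dict = field(default_factory=dict)


def fit_radial_peaks(
    profile: RadialProfile,
    primary: ReflectionSpec,
    cell: UnitCell,
    window: float = 1.5,
    centre_tolerance: float = 0.02,
) -> RadialFitResult:
    """Simultaneous Gaussian fit of the primary peak and its neighbours.

    All configured neighbours whose nominal q0 lies within ``+-window``
    (1/nm) of the primary are co-fitted on a shared linear local
    background; every centre is bounded to ``+-centre_tolerance``
    (fractional, default 2%) of its nominal position.  Overlapping
    neighbours left out of the fit bias the primary centre, so they are
    included rather than masked.
    """
    geom_p = ring_geometry(cell, primary)
    q0p = geom_p.q0_nominal
    lo, hi = q0p - window, q0p + window
    sel = (profile.q >= lo) & (profile.q <= hi) & profile.valid
    if sel.sum() < 8:
        raise ValueError("profile does not cover the primary fitting window")
    x = profile.q[sel]
    y = profile.intensity[sel]

    peaks = [("p", q0p)]
    for t, hkl in enumerate(primary.neighbours):
        spec = ReflectionSpec(*hkl)
        q0n = ring_geometry(cell, spec).q0_nominal
        if lo <= q0n <= hi:
            peaks.append((f"n{t}", q0n))

    params = lmfit.Parameters()
    base = float(np.percentile(y, 10))
    params.add("b0", value=base)
    params.add("b1", value=0.0)
    for name, q0 in peaks:
        amp0 = max(float(np.interp(q0, x, y)) - base, 1e-6)
        params.add(f"amp_{name}", value=amp0, min=0.0)
        params.add(
            f"cen_{name}", value=q0,
            min=q0 * (1 - centre_tolerance), max=q0 * (1 + centre_tolerance),
        )
        # widths bounded to the plausible microstrain-broadening range; an
        # unbounded neighbour otherwise drifts into a pseudo-background
        params.add(f"sig_{name}", value=0.2, min=0.02, max=0.6)

    def model(p):
        out = p["b0"] + p["b1"] * (x - q0p)
        for name, _ in peaks:
            out = out + p[f"amp_{name}"] * np.exp(
                -((x - p[f"cen_{name}"]) ** 2) / (2 * p[f"sig_{name}"] ** 2)
            )
        return out

    try:
        res = lmfit.minimize(lambda p: model(p) - y, params, method="leastsq")
        converged = bool(res.success)
        p = res.params
        redchi = float(res.redchi)
    except Exception:
        converged = False
        p = params
        redchi = math.nan

    cen = float(p["cen_p"].value)
    sig = float(p["sig_p"].value)
    amp = float(p["amp_p"].value)
    span = q0p * centre_tolerance
    at_bound = min(cen - (q0p - span), (q0p + span) - cen) < 1e-4 * q0p
    components = {
        name: {
            "q_centre": float(p[f"cen_{name}"].value),
            "sigma": float(p[f"sig_{name}"].value),
            "area": float(p[f"amp_{name}"].value)
            * float(p[f"sig_{name}"].value) * math.sqrt(2 * math.pi),
        }
        for name, _ in peaks
    }
    return RadialFitResult(
        label=primary.label,
        q_centre=cen,
        sigma=sig,
        area=amp * sig * math.sqrt(2 * math.pi),
        d_spacing=d_spacing(cen),
        converged=converged,
        at_bound=at_bound,
        redchi=redchi,
        components=components,
    )


# --- frame I/O -------------------------------------------------------------

def read_tiff(path) -> DetectorImage:
    """Read a single detector frame from TIFF (negative pixels masked)."""
    import tifffile

    counts = np.asarray(tifffile.imread(str(path)), dtype=float)
    mask = counts >= 0
    counts = np.where(mask, counts, 0.0)
    return DetectorImage(counts=counts, mask=mask)


def write_tiff(path, image: DetectorImage) -> None:
    import tifffile

    data = np.where(image.mask, image.counts, -1.0).astype(np.float32)
    tifffile.imwrite(str(path), data)


def read_h5_stack(path, dataset: str = "frames") -> list[DetectorImage]:
    """Read a scan stack from HDF5: datasets ``frames`` (n, rows, cols) and
    optional ``mask`` (rows, cols)."""
    import h5py

    with h5py.File(str(path), "r") as fh:
        frames = np.asarray(fh[dataset], dtype=float)
        mask = np.asarray(fh["mask"], dtype=bool) if "mask" in fh else None
    return [DetectorImage(counts=f, mask=None if mask is None else mask.copy())
            for f in frames]


def write_h5_stack(path, images: list[DetectorImage], dataset: str = "frames") -> None:
    import h5py

    stack = np.stack([im.counts for im in images])
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset(dataset, data=stack, compression="gzip")
        fh.create_dataset("mask", data=images[0].mask)
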