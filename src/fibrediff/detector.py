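"""Flat area-detector geometry: pixel grids, module gaps, (q, chi) maps.

Conventions
-----------
* The beam travels along +z; the detector plane is normal to the beam.
* Image arrays are indexed ``counts[row, col]`` with the row index
  increasing along lab +y (row 0 is the *bottom* of the detector) and the
  column index increasing along lab +x.  ``beam_centre`` is (x, y) in
  0-based pixel units in the same frame.
* Azimuth chi is measured counterclockwise from +x, in [0, 2pi).
* Hybrid pixel detectors are tiled from modules separated by insensitive
  gap strips; gap pixels are masked invalid, never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GapStrip",
    "DetectorGeometry",
    "DetectorImage",
    "pilatus_p3_2m",
    "eiger_4m",
    "get_preset",
    "polar_map",
]


@dataclass(frozen=True)
class GapStrip:
    """An insensitive strip of pixels spanning the full detector.

    axis='x' strips run vertically (block of columns); axis='y' strips run
    horizontally (block of rows).  ``start`` is the first gap pixel index,
    ``width`` the strip width in pixels.
    """

    axis: str
    start: int
    width: int

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.start < 0 or self.width <= 0:
            raise ValueError("invalid gap strip")


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector normal to the beam.

    Parameters
    ----------
    distance_mm : sample-to-detector distance.
    pixel_size_um : square pixel edge.
    beam_centre : (x, y) beam position, 0-based pixels, x right / y up.
    n_pixels : (columns, rows).
    gaps : module-gap strips; see :class:`GapStrip`.
    wavelength_nm : beam wavelength used for the pixel -> q mapping.
    """

    distance_mm: float
    pixel_size_um: float
    beam_centre: tuple[float, float]
    n_pixels: tuple[int, int]
    gaps: tuple[GapStrip, ...] = field(default_factory=tuple)
    wavelength_nm: float = 0.1
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.pixel_size_um <= 0:
            raise ValueError("distance and pixel size must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        ncol, nrow = self.n_pixels
        for g in self.gaps:
            bound = ncol if g.axis == "x" else nrow
            if g.start + g.width > bound:
                raise ValueError("gap strip outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) array shape."""
        return (self.n_pixels[1], self.n_pixels[0])

    def gap_mask(self) -> np.ndarray:
        """Boolean validity mask (True = live pixel), shape (rows, cols)."""
        nrow, ncol = self.shape
        valid = np.ones((nrow, ncol), dtype=bool)
        for g in self.gaps:
            if g.axis == "x":
                valid[:, g.start : g.start + g.width] = False
            else:
                valid[g.start : g.start + g.width, :] = False
        return valid

    def rebinned(self, factor: int) -> "DetectorGeometry":
        """Coarser geometry with the same physical extent and q-range.

        Pixel size grows by ``factor``; pixel counts, beam centre and gap
        strips shrink accordingly (gaps are kept at a minimum width of one
        coarse pixel).  Intended for fast simulations and tests.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        gaps = tuple(
            GapStrip(g.axis, g.start // factor, max(1, g.width // factor))
            for g in self.gaps
        )
        return replace(
            self,
            pixel_size_um=self.pixel_size_um * factor,
            beam_centre=(self.beam_centre[0] / factor, self.beam_centre[1] / factor),
            n_pixels=(self.n_pixels[0] // factor, self.n_pixels[1] // factor),
            gaps=gaps,
            name=f"{self.name}-bin{factor}",
        )


@dataclass
class DetectorImage:
    """Counts plus validity mask; gap pixels are invalid and zero."""

    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must match counts")


def polar_map(geometry: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel scattering-vector magnitude q (1/nm) and azimuth chi (rad).

    q follows from the scattering angle 2theta = arctan(r / distance) of the
    pixel centre at radial offset r from the beam centre:
    q = (4 pi / lambda) sin(theta).  chi = atan2(y, x) wrapped to [0, 2pi).
    """
    nrow, ncol = geometry.shape
    p_mm = geometry.pixel_size_um * 1e-3
    x = (np.arange(ncol) - geometry.beam_centre[0]) * p_mm
    y = (np.arange(nrow) - geometry.beam_centre[1]) * p_mm
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    theta = 0.5 * np.arctan2(r, geometry.distance_mm)
    q = (4.0 * math.pi / geometry.wavelength_nm) * np.sin(theta)
    chi = np.mod(np.arctan2(yy, xx), 2.0 * math.pi)
    return q, chi


def _tiled_gaps(axis: str, module: int, gap: int, n_modules: int) -> list[GapStrip]:
    return [
        GapStrip(axis, i * (module + gap) + module, gap) for i in range(n_modules - 1)
    ]


def pilatus_p3_2m(
    wavelength_nm: float = 1.2398 / 14.0,
    distance_mm: float = 296.0,
    beam_centre: tuple[float, float] | None = None,
) -> DetectorGeometry:
    """Pilatus P3-2M: 1475 x 1679 px of 172 um; 3 x 8 modules of 487 x 195 px
    with 7-px (horizontal) and 17-px (vertical) gaps.  Defaults match a
    14 keV beam at 296 mm with the beam at the detector centre."""
    n_pixels = (1475, 1679)
    if beam_centre is None:
        beam_centre = ((n_pixels[0] - 1) / 2, (n_pixels[1] - 1) / 2)
    gaps = _tiled_gaps("x", 487, 7, 3) + _tiled_gaps("y", 195, 17, 8)
    return DetectorGeometry(
        distance_mm=distance_mm,
        pixel_size_um=172.0,
        beam_centre=beam_centre,
        n_pixels=n_pixels,
        gaps=tuple(gaps),
        wavelength_nm=wavelength_nm,
        name="pilatus-p3-2m",
    )


def eiger_4m(
    wavelength_nm: float = 1.2398 / 17.0,
    distance_mm: float = 166.0,
    beam_centre: tuple[float, float] | None = None,
) -> DetectorGeometry:
    """Eiger 4M: 2070 x 2167 px of 75 um; 2 x 4 modules of 1030 x 514 px with
    10-px (horizontal) and 37-px (vertical) gaps.  Defaults match a 17 keV
    beam at 166 mm with the beam at the detector centre."""
    n_pixels = (2070, 2167)
    if beam_centre is None:
        beam_centre = ((n_pixels[0] - 1) / 2, (n_pixels[1] - 1) / 2)
    gaps = _tiled_gaps("x", 1030, 10, 2) + _tiled_gaps("y", 514, 37, 4)
    return DetectorGeometry(
        distance_mm=distance_mm,
        pixel_size_um=75.0,
        beam_centre=beam_centre,
        n_pixels=n_pixels,
        gaps=tuple(gaps),
        wavelength_nm=wavelength_nm,
        name="eiger-4m",
    )


_PRESETS = {"pilatus-p3-2m": pilatus_p3_2m, "eiger-4m": eiger_4m}


def get_preset(name: str, **kwargs) -> DetectorGeometry:
    """Look up a named detector preset ('pilatus-p3-2m' or 'eiger-4m')."""
    try:
        return _PRESETS[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown detector preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
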