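"""Orthorhombic reciprocal-lattice geometry for fibre-symmetric crystals.

Under fibre symmetry each reciprocal-lattice node (hkl) is smeared into a
ring around the fibre (c) axis.  This module maps an orthorhombic unit cell
and a Miller triple onto the two quantities the diffraction model needs:
the ring opening angle ``mu`` (angle between the ring and the c axis, in
[0, pi/2]) and the nominal ring radius ``q0`` (the reciprocal-vector
magnitude).  The mirror ring at ``pi - mu`` for (0kl) reflections is a
property of the band intensity profile, not a second geometry object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitCell",
    "ReflectionSpec",
    "ReflectionGeometry",
    "ALPHA_CHITIN_CELL",
    "CHITIN_REFLECTIONS",
    "reciprocal_vector",
    "ring_geometry",
    "d_spacing",
]


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic unit cell; ``c`` is along the fibril axis.

    Parameters
    ----------
    a, b, c : float
        Lattice constants in nm; all strictly positive.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("lattice constants must be positive")


@dataclass(frozen=True)
class ReflectionSpec:
    """A named (hkl) reflection with its reduction metadata.

    ``radial_band`` is the [q_min, q_max] integration window in 1/nm and
    ``neighbours`` lists Miller triples co-fitted with this reflection in
    radial multi-peak fits (overlapping rings shift an isolated-peak fit).
    """

    h: int
    k: int
    l: int
    label: str = ""
    radial_band: tuple[float, float] | None = None
    neighbours: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("(0,0,0) is not a reflection")
        if self.radial_band is not None and not (
            self.radial_band[0] < self.radial_band[1]
        ):
            raise ValueError("radial_band must satisfy q_min < q_max")
        if not self.label:
            object.__setattr__(self, "label", f"{self.h}{self.k}{self.l}")

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass(frozen=True)
class ReflectionGeometry:
    """Ring opening angle ``mu`` (rad, in [0, pi/2]) and nominal radius ``q0`` (1/nm)."""

    mu: float
    q0_nominal: float


def reciprocal_vector(cell: UnitCell, refl: ReflectionSpec) -> np.ndarray:
    """Reciprocal-lattice vector (h 2pi/a, k 2pi/b, l 2pi/c) in 1/nm.

    Components are expressed in the fibre frame with the third axis along c.
    """
    return 2.0 * math.pi * np.array(
        [refl.h / cell.a, refl.k / cell.b, refl.l / cell.c]
    )


def ring_geometry(cell: UnitCell, refl: ReflectionSpec) -> ReflectionGeometry:
    """Opening angle and nominal radius of the (hkl) fibre-symmetry ring.

    ``mu`` is the angle between the reciprocal vector and the c axis,
    folded into [0, pi/2]: 0 for axial (00l), pi/2 for equatorial (hk0).
    """
    g = reciprocal_vector(cell, refl)
    q0 = float(np.linalg.norm(g))
    # |g_c|/|g| clamped against rounding before arccos
    c_frac = min(1.0, abs(g[2]) / q0)
    return ReflectionGeometry(mu=math.acos(c_frac), q0_nominal=q0)


def d_spacing(q: float) -> float:
    """Lattice spacing d = 2pi/q (nm for q in 1/nm)."""
    q = float(q)
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * math.pi / q


# Standard literature cell for alpha-chitin (orthorhombic, c = fibre axis),
# consistent with the (002)/(110)/(013) radial windows used in reduction.
ALPHA_CHITIN_CELL = UnitCell(a=0.474, b=1.886, c=1.032)

CHITIN_REFLECTIONS: dict[str, ReflectionSpec] = {
    "002": ReflectionSpec(0, 0, 2, "002", radial_band=(11.8, 12.8)),
    "110": ReflectionSpec(
        1, 1, 0, "110",
        radial_band=(12.8, 15.5),
        neighbours=((0, 0, 2), (0, 1, 2), (1, 0, 0), (1, 0, 1), (1, 2, 0), (1, 1, 1)),
    ),
    "013": ReflectionSpec(0, 1, 3, "013", radial_band=(18.0, 19.2)),
}
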