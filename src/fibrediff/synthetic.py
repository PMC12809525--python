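"""Synthetic detector frames and raster scans with known ground truth.

Emulates the measurement conditions of scanning WAXD on Bouligand cuticle:
a plywood stack whose in-plane fibre angle advances linearly with depth,
rendered through the forward model onto Pilatus-/Eiger-style detector
geometries (module gaps masked), with optional Poisson counting noise and
an optional smooth diffuse background.  Every generated artefact is
accompanied by its ground-truth table; all randomness flows from one
explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detector import DetectorGeometry, DetectorImage, polar_map
from .forward import (
    DEFAULT_N_GAMMA,
    BeamGeometry,
    GammaModel,
    Orientation,
    PeakShape,
    render_pattern,
)
from .lattice import (
    ALPHA_CHITIN_CELL,
    CHITIN_REFLECTIONS,
    ReflectionGeometry,
    UnitCell,
    ring_geometry,
)

__all__ = [
    "BouligandStack",
    "NoiseModel",
    "orientation_at_depth",
    "simulate_frame",
    "simulate_scan",
    "default_shapes",
]


@dataclass(frozen=True)
class BouligandStack:
    """Plywood stack: in-plane fibre angle rotates linearly with depth.

    rotation_pitch is in degrees of in-plane rotation per micrometre; a
    60 um lamella at 3 deg/um sweeps the full 180 deg period.  Fibril
    misalignment (the w_mu multiplier) is elevated within
    ``boundary_zone_um`` of each lamella interface by
    ``interface_misalignment_boost``.
    """

    n_lamellae: int = 5
    lamella_thicknesses_um: tuple[float, ...] = ()
    rotation_pitch_deg_per_um: float = 3.0
    stack_tilt: tuple[float, float] = (0.0, 0.0)
    interface_misalignment_boost: float = 1.5
    boundary_zone_um: float = 3.0
    gamma_start: float = 0.0

    def __post_init__(self) -> None:
        if not self.lamella_thicknesses_um:
            object.__setattr__(
                self, "lamella_thicknesses_um", (60.0,) * self.n_lamellae
            )
        if len(self.lamella_thicknesses_um) != self.n_lamellae:
            raise ValueError("need one thickness per lamella")
        if any(t <= 0 for t in self.lamella_thicknesses_um):
            raise ValueError("thicknesses must be positive")
        if not math.isfinite(self.rotation_pitch_deg_per_um):
            raise ValueError("pitch must be finite")

    @property
    def total_thickness_um(self) -> float:
        return float(sum(self.lamella_thicknesses_um))


def orientation_at_depth(
    stack: BouligandStack, z_um: float
) -> tuple[float, float, float, float]:
    """(gamma, alpha, beta, w_mu multiplier) at depth z (um) into the stack.

    gamma advances linearly at the rotation pitch, wrapping with period pi;
    the stack tilt is constant; the w_mu multiplier is boosted near lamella
    interfaces.
    """
    if not (0.0 <= z_um <= stack.total_thickness_um):
        raise ValueError("depth outside the stack")
    gamma = (
        stack.gamma_start
        + math.radians(stack.rotation_pitch_deg_per_um) * z_um
    ) % math.pi
    mult = 1.0
    edges = np.cumsum((0.0,) + stack.lamella_thicknesses_um)
    inner = edges[1:-1]  # interfaces between lamellae
    if inner.size and np.min(np.abs(inner - z_um)) <= stack.boundary_zone_um:
        mult = stack.interface_misalignment_boost
    return gamma, stack.stack_tilt[0], stack.stack_tilt[1], mult


@dataclass(frozen=True)
class NoiseModel:
    """Exposure scaling and optional Poisson counting noise.

    Identical seed implies identical frames.
    """

    exposure_scale: float = 1.0
    poisson: bool = True
    seed: int = 0


def default_shapes(
    cell: UnitCell = ALPHA_CHITIN_CELL,
    amplitudes: dict[str, float] | None = None,
    w_mus_deg: dict[str, float] | None = None,
    dq: float = 0.35,
) -> tuple[list[ReflectionGeometry], list[PeakShape], list[str]]:
    """Ring geometries and realistic peak shapes for the chitin reflections.

    The equatorial (110) is the brightest and angularly broadest; the axial
    (002) is sharp; widths default to a few degrees of intrinsic fibril
    misalignment.
    """
    amplitudes = amplitudes or {"002": 600.0, "110": 1000.0, "013": 400.0}
    w_mus_deg = w_mus_deg or {"002": 5.0, "110": 8.0, "013": 5.0}
    geoms, shapes, labels = [], [], []
    for lab, spec in CHITIN_REFLECTIONS.items():
        g = ring_geometry(cell, spec)
        geoms.append(g)
        shapes.append(
            PeakShape(
                amplitude=amplitudes.get(lab, 500.0),
                w_mu=math.radians(w_mus_deg.get(lab, 5.0)),
                q0=g.q0_nominal,
                dq=dq,
            )
        )
        labels.append(lab)
    return geoms, shapes, labels


def _diffuse_background(
    geometry: DetectorGeometry, coefficients: tuple[float, ...]
) -> np.ndarray:
    """Smooth radial polynomial background sum_i c_i (q/10)^i."""
    q, _ = polar_map(geometry)
    out = np.zeros_like(q)
    for i, c in enumerate(coefficients):
        out += c * (q / 10.0) ** i
    return out


def simulate_frame(
    orientation: Orientation,
    gamma_model: GammaModel,
    geometry: DetectorGeometry,
    reflections: list[ReflectionGeometry],
    shapes: list[PeakShape],
    noise: NoiseModel | None = None,
    beam: BeamGeometry | None = None,
    background_coefficients: tuple[float, ...] = (),
    n_gamma: int = DEFAULT_N_GAMMA,
) -> DetectorImage:
    """Render one frame: expected counts = exposure x model intensity
    (+ optional diffuse background), then Poisson sampling when enabled.

    Gap pixels are zeroed and masked per the detector geometry.
    """
    noise = noise or NoiseModel(poisson=False)
    image = render_pattern(
        geometry, reflections, shapes, orientation, gamma_model, beam,
        n_gamma=n_gamma,
    )
    expected = image.counts * noise.exposure_scale
    if background_coefficients:
        expected = expected + _diffuse_background(geometry, background_coefficients)
        expected[~image.mask] = 0.0
    if noise.poisson:
        rng = np.random.default_rng(noise.seed)
        counts = rng.poisson(np.clip(expected, 0.0, None)).astype(float)
        counts[~image.mask] = 0.0
    else:
        counts = expected
    return DetectorImage(counts=counts, mask=image.mask)


def simulate_scan(
    stack: BouligandStack,
    geometry: DetectorGeometry,
    step_um: float = 3.0,
    n_points: int | None = None,
    n_cols: int = 1,
    col_step_um: float = 7.0,
    base_shapes: tuple | None = None,
    noise: NoiseModel | None = None,
    beam: BeamGeometry | None = None,
    background_coefficients: tuple[float, ...] = (),
    n_gamma: int = DEFAULT_N_GAMMA,
) -> tuple[list[DetectorImage], pd.DataFrame]:
    """Simulate a raster scan through the stack depth.

    Rows step through depth at ``step_um``; ``n_cols`` identical columns
    emulate the lateral scan axis.  Each point is a delta-distributed
    single fibre direction given by ``orientation_at_depth``.  Returns the
    frame list (row-major) and a ground-truth table aligned with it.
    """
    if step_um <= 0 or col_step_um <= 0:
        raise ValueError("steps must be positive")
    noise = noise or NoiseModel(poisson=False)
    if base_shapes is None:
        base_shapes = default_shapes()
    geoms, shapes, labels = base_shapes
    if n_points is None:
        n_points = int(stack.total_thickness_um // step_um) + 1
    frames: list[DetectorImage] = []
    truth_rows = []
    for r in range(n_points):
        z = min(r * step_um, stack.total_thickness_um)
        gamma, alpha, beta, mult = orientation_at_depth(stack, z)
        orient = Orientation(alpha, beta)
        gm = GammaModel("delta", gamma0=gamma)
        point_shapes = [
            PeakShape(s.amplitude, s.w_mu * mult, s.q0, s.dq) for s in shapes
        ]
        for c in range(n_cols):
            frame_seed = (noise.seed * 1_000_003 + r * n_cols + c) % (2**31)
            frames.append(
                simulate_frame(
                    orient, gm, geometry, geoms, point_shapes,
                    NoiseModel(noise.exposure_scale, noise.poisson, frame_seed),
                    beam=beam,
                    background_coefficients=background_coefficients,
                    n_gamma=n_gamma,
                )
            )
            truth_rows.append(
                {
                    "row": r,
                    "col": c,
                    "x_um": c * col_step_um,
                    "z_um": z,
                    "gamma": gamma,
                    "alpha": alpha,
                    "beta": beta,
                    "w_mu_multiplier": mult,
                    "seed": frame_seed,
                    **{
                        f"w_mu_{lab}": s.w_mu
                        for lab, s in zip(labels, point_shapes)
                    },
                    **{
                        f"bg_c{i}": c_
                        for i, c_ in enumerate(background_coefficients)
                    },
                }
            )
    return frames, pd.DataFrame(truth_rows)
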