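"""TOML run configuration: unit cell, beam, detector, reflections, fit options.

Angles are degrees in config files and radians internally; q values are
1/nm.  Every section is optional and falls back to the chitin defaults, so
a minimal config can be empty.  ``resolve()`` returns the fully populated
dictionary that runs write next to their outputs for reproducibility.
"""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path

from .detector import DetectorGeometry, GapStrip, get_preset
from .forward import BeamGeometry, GammaModel, Orientation
from .fitting import JointFitConfig
from .lattice import ALPHA_CHITIN_CELL, CHITIN_REFLECTIONS, ReflectionSpec, UnitCell

__all__ = [
    "load_config",
    "cell_from_config",
    "beam_from_config",
    "detector_from_config",
    "reflections_from_config",
    "orientation_from_config",
    "gamma_from_config",
    "fit_config_from_config",
    "write_resolved_config",
]


def load_config(path) -> dict:
    with open(str(path), "rb") as fh:
        return tomllib.load(fh)


def cell_from_config(cfg: dict) -> UnitCell:
    sec = cfg.get("cell", {})
    return UnitCell(
        a=sec.get("a_nm", ALPHA_CHITIN_CELL.a),
        b=sec.get("b_nm", ALPHA_CHITIN_CELL.b),
        c=sec.get("c_nm", ALPHA_CHITIN_CELL.c),
    )


def beam_from_config(cfg: dict) -> BeamGeometry:
    sec = cfg.get("beam", {})
    if "wavelength_nm" in sec:
        return BeamGeometry(sec["wavelength_nm"])
    if "energy_kev" in sec:
        return BeamGeometry.from_energy_kev(sec["energy_kev"])
    return BeamGeometry.from_energy_kev(14.0)


def detector_from_config(cfg: dict) -> DetectorGeometry:
    sec = cfg.get("detector", {})
    wavelength = beam_from_config(cfg).wavelength_nm
    if "preset" in sec:
        kwargs = {"wavelength_nm": wavelength}
        if "distance_mm" in sec:
            kwargs["distance_mm"] = sec["distance_mm"]
        if "beam_centre" in sec:
            kwargs["beam_centre"] = tuple(sec["beam_centre"])
        geom = get_preset(sec["preset"], **kwargs)
    elif sec:
        gaps = tuple(
            GapStrip(g["axis"], g["start"], g["width"]) for g in sec.get("gaps", [])
        )
        n_pixels = tuple(sec.get("n_pixels", (256, 256)))
        geom = DetectorGeometry(
            distance_mm=sec.get("distance_mm", 296.0),
            pixel_size_um=sec.get("pixel_size_um", 172.0),
            beam_centre=tuple(
                sec.get("beam_centre", ((n_pixels[0] - 1) / 2, (n_pixels[1] - 1) / 2))
            ),
            n_pixels=n_pixels,
            gaps=gaps,
            wavelength_nm=wavelength,
        )
    else:
        geom = get_preset("pilatus-p3-2m", wavelength_nm=wavelength)
    rebin = sec.get("rebin", 1)
    if rebin > 1:
        geom = geom.rebinned(int(rebin))
    return geom


def reflections_from_config(cfg: dict) -> dict[str, ReflectionSpec]:
    entries = cfg.get("reflections", [])
    if not entries:
        return dict(CHITIN_REFLECTIONS)
    out = {}
    for e in entries:
        h, k, l = e["hkl"]
        spec = ReflectionSpec(
            h, k, l,
            label=e.get("label", f"{h}{k}{l}"),
            radial_band=tuple(e["radial_band"]) if "radial_band" in e else None,
            neighbours=tuple(tuple(t) for t in e.get("neighbours", [])),
        )
        out[spec.label] = spec
    return out


def orientation_from_config(cfg: dict) -> Orientation:
    sec = cfg.get("orientation", {})
    return Orientation(
        alpha=math.radians(sec.get("alpha_deg", 0.0)),
        beta=math.radians(sec.get("beta_deg", 0.0)),
    )


def gamma_from_config(cfg: dict) -> GammaModel:
    sec = cfg.get("gamma", {})
    kind = sec.get("kind", "uniform")
    kwargs = {"gamma0": math.radians(sec.get("gamma0_deg", 90.0))}
    if kind == "gaussian":
        kwargs["delta_gamma0"] = math.radians(sec.get("delta_gamma0_deg", 5.0))
    return GammaModel(kind, **kwargs)


def fit_config_from_config(cfg: dict) -> JointFitConfig:
    sec = cfg.get("fit", {})
    return JointFitConfig(
        mode=sec.get("mode", "L1_uniform"),
        visibility_threshold=sec.get("visibility_threshold", 0.05),
        poisson_weights=sec.get("poisson_weights", False),
        max_iter=sec.get("max_iter", 4000),
        tolerance=sec.get("tolerance", 1e-8),
        n_gamma=sec.get("n_gamma", 181),
    )


def resolve(cfg: dict) -> dict:
    """Fully populated configuration actually used by a run."""
    cell = cell_from_config(cfg)
    beam = beam_from_config(cfg)
    det = detector_from_config(cfg)
    refl = reflections_from_config(cfg)
    orient = orientation_from_config(cfg)
    gm = gamma_from_config(cfg)
    fit = fit_config_from_config(cfg)
    return {
        "schema_version": 1,
        "cell": {"a_nm": cell.a, "b_nm": cell.b, "c_nm": cell.c},
        "beam": {"wavelength_nm": beam.wavelength_nm},
        "detector": {
            "name": det.name,
            "distance_mm": det.distance_mm,
            "pixel_size_um": det.pixel_size_um,
            "beam_centre": list(det.beam_centre),
            "n_pixels": list(det.n_pixels),
            "gaps": [
                {"axis": g.axis, "start": g.start, "width": g.width}
                for g in det.gaps
            ],
        },
        "reflections": {
            lab: {
                "hkl": list(s.hkl),
                "radial_band": list(s.radial_band) if s.radial_band else None,
                "neighbours": [list(t) for t in s.neighbours],
            }
            for lab, s in refl.items()
        },
        "orientation": {
            "alpha_deg": math.degrees(orient.alpha),
            "beta_deg": math.degrees(orient.beta),
        },
        "gamma": {
            "kind": gm.kind,
            "gamma0_deg": math.degrees(gm.gamma0),
            "delta_gamma0_deg": math.degrees(gm.delta_gamma0)
            if gm.delta_gamma0 else None,
        },
        "fit": {
            "mode": fit.mode,
            "visibility_threshold": fit.visibility_threshold,
            "poisson_weights": fit.poisson_weights,
            "max_iter": fit.max_iter,
            "tolerance": fit.tolerance,
            "n_gamma": fit.n_gamma,
        },
    }


def write_resolved_config(cfg: dict, out_dir) -> Path:
    """Write the resolved configuration next to a run's outputs."""
    path = Path(out_dir) / "resolved_config.json"
    with open(path, "w") as fh:
        json.dump(resolve(cfg), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
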