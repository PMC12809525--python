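"""Shared-parameter joint fitting of multi-reflection azimuthal profiles.

The estimation problem: given background-corrected azimuthal profiles
I(chi) of several reflections (typically the axial (002), equatorial (110)
and general (013)), recover the 3D fibre-array orientation and per-
reflection amplitude and angular dispersion.  Two modes:

* ``L1_uniform`` — the beam traverses a full Bouligand stack, so the
  in-plane distribution is uniform, w(gamma) = 1/pi; free parameters are
  the shared tilts (alpha, beta) plus per-reflection (N, w_mu).
* ``L3_delta`` — each probed sublamella has a single fibre direction,
  w(gamma) a Dirac delta; gamma0 joins the shared parameters.

The tilt pair is shared across all reflection residuals and minimized by
Nelder-Mead simplex over the valid chi bins.  Reflections whose peak
counts fall below a visibility threshold (they may not intersect the Ewald
sphere at large tilt, or fall into module gaps) are excluded from the
residual and recorded.

The module follows a Model/Results layout: build a
:class:`JointAzimuthalModel` from profiles, call ``fit()``, and read the
estimates, uncertainties and ``summary()`` off the returned
:class:`JointFitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .detector import DetectorGeometry, DetectorImage
from .estimators import (
    NoPeakError,
    TiltDecomposition,
    alpha_beta_from_direction,
    compose_orientation,
    decompose_orientation,
    summarize_profile,
)
from .forward import (
    DEFAULT_N_GAMMA,
    BeamGeometry,
    GammaModel,
    Orientation,
)
from .lattice import (
    CHITIN_REFLECTIONS,
    ReflectionGeometry,
    ReflectionSpec,
    UnitCell,
    ring_geometry,
)
from .profiles import AzimuthalProfile
from .reduction import (
    azimuthal_integrate,
    fit_radial_peaks,
    radial_integrate,
    ring_background_subtract,
)

__all__ = [
    "JointFitConfig",
    "JointAzimuthalModel",
    "JointFitResult",
    "initial_guess",
    "fit_scan",
    "ScanResult",
    "export_orientation_glyphs",
]

W_MU_MIN = math.radians(0.2)
W_MU_MAX = math.radians(60.0)


@dataclass(frozen=True)
class JointFitConfig:
    """Options for the joint azimuthal fit.

    mode selects the in-plane distribution ('L1_uniform' or 'L3_delta');
    visibility_threshold is the fraction of the reference reflection's peak
    counts below which a reflection is dropped from the residual;
    poisson_weights switches the unweighted least squares default to
    1/sqrt(counts) weighting; n_gamma is the gamma-quadrature order for the
    uniform mode.
    """

    mode: str = "L1_uniform"
    visibility_threshold: float = 0.05
    poisson_weights: bool = False
    max_iter: int = 4000
    tolerance: float = 1e-8
    n_gamma: int = DEFAULT_N_GAMMA

    def __post_init__(self) -> None:
        if self.mode not in ("L1_uniform", "L3_delta"):
            raise ValueError("mode must be 'L1_uniform' or 'L3_delta'")


def initial_guess(
    profiles: dict[str, AzimuthalProfile],
    geoms: dict[str, ReflectionGeometry],
    beam: BeamGeometry,
    config: JointFitConfig,
) -> dict[str, float]:
    """Seed parameters from profile summaries.

    L3: the equatorial peak pair gives the in-plane fibre angle (peaks sit
    perpendicular to the fibre) and the peak-separation deviation the sense
    of the out-of-plane tilt.  L1: a coarse grid search over tilt azimuth
    and magnitude of the array normal.  Flat or missing profiles fall back
    to zero tilt.  Per-reflection amplitudes seed from peak counts and
    widths from profile FWHM.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    seed: dict[str, float] = {"alpha": 0.0, "beta": 0.0}
    if config.mode == "L3_delta":
        seed["gamma0"] = math.pi / 2
        seed["alpha_prime"] = 0.0
    # per-reflection amplitude and width seeds
    for label, prof in profiles.items():
        peak = prof.max_valid()
        seed[f"N_{label}"] = max(peak, 1e-6)
        w = math.radians(8.0)
        try:
            s = summarize_profile(prof)
            fw = s.fwhm
            fw = fw[np.isfinite(fw)]
            if fw.size:
                w = float(np.clip(np.mean(fw) / 2.0, W_MU_MIN * 2, W_MU_MAX * 0.9))
        except NoPeakError:
            pass
        seed[f"w_mu_{label}"] = w

    equatorial = [
        lab for lab, g in geoms.items()
        if lab in profiles and abs(g.mu - math.pi / 2) < 1e-6
    ]
    if config.mode == "L3_delta" and equatorial:
        lab = equatorial[0]
        try:
            s = summarize_profile(profiles[lab], upper_chi=math.pi, lower_chi=0.0)
            if len(s.positions) >= 2:
                i = np.argsort(s.heights)[-2:]
                p = np.sort(s.positions[i])
                # equatorial peaks flank the fibre axis at +-90 deg, so
                # their midpoint is the fibre angle modulo the pi period
                seed["gamma0"] = (0.5 * (p[0] + p[1])) % math.pi
        except NoPeakError:
            pass
    return seed


def _coarse_tilt_scan(model: "JointAzimuthalModel", seed: dict[str, float]) -> dict:
    """Grid search over tilt azimuth/magnitude of the array normal (L1)."""
    best = dict(seed)
    best_cost = model._cost(seed)
    for tau_deg in (5, 10, 15, 20, 25, 30):
        tau = math.radians(tau_deg)
        for psi in np.linspace(0, 2 * math.pi, 12, endpoint=False):
            m = np.array(
                [math.sin(tau) * math.cos(psi),
                 math.sin(tau) * math.sin(psi),
                 math.cos(tau)]
            )
            # array normal m = (sin b, -sin a cos b, cos a cos b)
            beta = math.asin(np.clip(m[0], -1, 1))
            cb = math.cos(beta)
            alpha = math.atan2(-m[1] / cb, m[2] / cb) if cb > 1e-9 else 0.0
            trial = dict(seed)
            trial["alpha"], trial["beta"] = alpha, beta
            c = model._cost(trial)
            if c < best_cost:
                best_cost, best = c, trial
    return best


class JointAzimuthalModel:
    """Joint model of multi-reflection azimuthal profiles.

    Parameters
    ----------
    profiles : dict label -> AzimuthalProfile (background-corrected).
    geoms : dict label -> ReflectionGeometry (must share labels).
    beam : BeamGeometry.
    config : JointFitConfig.
    """

    def __init__(
        self,
        profiles: dict[str, AzimuthalProfile],
        geoms: dict[str, ReflectionGeometry],
        beam: BeamGeometry,
        config: JointFitConfig | None = None,
    ) -> None:
        if not profiles:
            raise ValueError("at least one profile required")
        missing = set(profiles) - set(geoms)
        if missing:
            raise ValueError(f"missing ring geometry for {sorted(missing)}")
        self.profiles = dict(profiles)
        self.geoms = {k: geoms[k] for k in profiles}
        self.beam = beam
        self.config = config or JointFitConfig()
        self.reflections_used = self._select_visible()
        self._scales = {k: (p.max_valid() or 1.0) for k, p in self.profiles.items()}
        self._Q_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_reflections(
        cls,
        profiles: dict[str, AzimuthalProfile],
        cell: UnitCell,
        specs: dict[str, ReflectionSpec],
        beam: BeamGeometry,
        config: JointFitConfig | None = None,
    ) -> "JointAzimuthalModel":
        geoms = {lab: ring_geometry(cell, spec) for lab, spec in specs.items()}
        return cls(profiles, geoms, beam, config)

    def _select_visible(self) -> list[str]:
        """Drop reflections whose peak counts are below the visibility
        threshold relative to the equatorial (else brightest) reflection."""
        peaks = {lab: p.max_valid() for lab, p in self.profiles.items()}
        eq = [
            lab for lab, g in self.geoms.items()
            if abs(g.mu - math.pi / 2) < 1e-6 and peaks[lab] > 0
        ]
        ref = peaks[eq[0]] if eq else max(peaks.values(), default=0.0)
        if ref <= 0:
            return []
        thr = self.config.visibility_threshold * ref
        return [lab for lab, pk in peaks.items() if pk >= thr]

    def _ewald(self, label: str) -> np.ndarray:
        from .forward import ewald_vector

        if label not in self._Q_cache:
            self._Q_cache[label] = ewald_vector(
                self.geoms[label].q0_nominal, self.profiles[label].chi, self.beam
            )
        return self._Q_cache[label]

    def fibre_axis_from_params(self, params: dict[str, float]) -> np.ndarray:
        """Unit fibre direction implied by L3 parameters (gamma0, alpha')."""
        return compose_orientation(
            TiltDecomposition(
                gamma=params["gamma0"] - math.pi / 2,
                alpha_prime=params["alpha_prime"],
            )
        )

    def profile_model(self, label: str, params: dict[str, float]) -> np.ndarray:
        """Model intensity for one reflection at its data chi bins.

        L1 integrates over the uniform in-plane distribution at the shared
        (alpha, beta); L3 evaluates the single-fibril intensity for the
        direction given by (gamma0, alpha').
        """
        from .forward import PeakShape, array_intensity, single_fibril_intensity

        geom = self.geoms[label]
        shape = PeakShape(
            amplitude=params[f"N_{label}"],
            w_mu=params[f"w_mu_{label}"],
            q0=geom.q0_nominal,
            dq=1.0,
        )
        Q = self._ewald(label)
        if self.config.mode == "L3_delta":
            n = self.fibre_axis_from_params(params)
            return single_fibril_intensity(Q, n, geom, shape)
        orient = Orientation(params["alpha"], params["beta"])
        return array_intensity(
            Q, orient, GammaModel("uniform"), geom, shape,
            n_gamma=self.config.n_gamma,
        )

    def _solve_amplitudes(self, params: dict[str, float]) -> dict[str, float]:
        """Per-reflection amplitudes by linear least squares at the current
        nonlinear parameters (variable projection): the model is linear in
        each N, so N never needs to ride in the simplex."""
        out = {}
        for label in self.reflections_used:
            prof = self.profiles[label]
            p1 = dict(params)
            p1[f"N_{label}"] = 1.0
            m1 = self.profile_model(label, p1)[prof.valid]
            y = prof.intensity[prof.valid]
            if self.config.poisson_weights:
                w = 1.0 / np.maximum(y, 1.0)
            else:
                w = np.ones_like(y)
            denom = float(np.sum(w * m1 * m1))
            num = float(np.sum(w * m1 * y))
            out[f"N_{label}"] = max(num / denom, 0.0) if denom > 0 else 0.0
        return out

    def _residual_vector(self, params: dict[str, float]) -> np.ndarray:
        """Residuals normalized per reflection by its peak counts, so the
        cost is O(1) regardless of exposure.  Amplitudes absent from
        ``params`` are profiled out by linear least squares."""
        need_amp = any(
            f"N_{label}" not in params for label in self.reflections_used
        )
        if need_amp:
            params = {**params, **self._solve_amplitudes(params)}
        res = []
        for label in self.reflections_used:
            prof = self.profiles[label]
            scale = self._scales[label]
            model = self.profile_model(label, params)
            r = (model - prof.intensity)[prof.valid] / scale
            if self.config.poisson_weights:
                r = r * scale / np.sqrt(np.maximum(prof.intensity[prof.valid], 1.0))
            res.append(r)
        return np.concatenate(res) if res else np.array([0.0])

    def _cost(self, params: dict[str, float]) -> float:
        r = self._residual_vector(params)
        return float(r @ r)

    def _free_names(self) -> list[str]:
        if self.config.mode == "L3_delta":
            names = ["gamma0", "alpha_prime"]
        else:
            names = ["alpha", "beta"]
        for label in self.reflections_used:
            names += [f"N_{label}", f"w_mu_{label}"]
        return names

    def fit(self, start: dict[str, float] | None = None) -> "JointFitResult":
        """Minimize the summed squared residuals by Nelder-Mead simplex."""
        if not self.reflections_used:
            raise ValueError("no reflection above the visibility threshold")
        if start is None:
            start = initial_guess(
                {k: self.profiles[k] for k in self.reflections_used},
                self.geoms, self.beam, self.config,
            )
            if self.config.mode == "L1_uniform":
                start = _coarse_tilt_scan(self, start)
        params = lmfit.Parameters()
        half_pi = math.pi / 2
        if self.config.mode == "L3_delta":
            # 2-dof direction: in-plane fibre angle + single out-of-plane
            # tilt ((gamma, alpha') picture); (alpha, beta) are derived
            g0 = start.get("gamma0", half_pi) % math.pi
            params.add("gamma0", value=g0, min=g0 - half_pi, max=g0 + half_pi)
            params.add(
                "alpha_prime", value=start.get("alpha_prime", 0.0),
                min=-half_pi * 0.999, max=half_pi * 0.999,
            )
        else:
            params.add("alpha", value=start.get("alpha", 0.0),
                       min=-half_pi, max=half_pi)
            params.add("beta", value=start.get("beta", 0.0),
                       min=-half_pi, max=half_pi)
        for label in self.reflections_used:
            # amplitudes are profiled out (variable projection); only the
            # angular widths join the tilt angles in the simplex
            params.add(
                f"w_mu_{label}",
                value=float(np.clip(start.get(f"w_mu_{label}", math.radians(8)),
                                    W_MU_MIN * 1.01, W_MU_MAX * 0.99)),
                min=W_MU_MIN, max=W_MU_MAX,
            )

        def residual(p):
            return self._residual_vector({k: float(p[k].value) for k in p})

        out = lmfit.minimize(
            residual, params, method="nelder",
            max_nfev=self.config.max_iter * max(len(params), 1),
            options={"xatol": self.config.tolerance ** 0.5,
                     "fatol": self.config.tolerance},
        )
        values = {k: float(out.params[k].value) for k in out.params}
        if self.config.mode == "L3_delta":
            values["gamma0"] %= math.pi
        values.update(self._solve_amplitudes(values))
        stderr = self._covariance_stderr(values)
        if self.config.mode == "L3_delta":
            self._derive_alpha_beta(values, stderr)
        resid = self._residual_vector(values)
        return JointFitResult(
            model=self,
            params=values,
            stderr=stderr,
            residual_norm=float(np.sqrt(resid @ resid)),
            n_points=int(resid.size),
            success=bool(out.success),
            reflections_used=list(self.reflections_used),
            mode=self.config.mode,
        )

    def _derive_alpha_beta(
        self, values: dict[str, float], stderr: dict[str, float]
    ) -> None:
        """Express the fitted L3 direction as the equivalent (alpha, beta)
        tilt pair at the fitted in-plane angle, with uncertainties
        propagated by finite differences (correlations neglected)."""
        def ab(g0: float, ap: float) -> tuple[float, float]:
            n = compose_orientation(
                TiltDecomposition(gamma=g0 - math.pi / 2, alpha_prime=ap)
            )
            o = alpha_beta_from_direction(n, g0)
            return o.alpha, o.beta

        a0, b0 = ab(values["gamma0"], values["alpha_prime"])
        values["alpha"], values["beta"] = a0, b0
        h = 1e-5
        var_a = var_b = 0.0
        for name in ("gamma0", "alpha_prime"):
            s = stderr.get(name, math.nan)
            if not math.isfinite(s):
                continue
            up = dict(values)
            up[name] += h
            a1, b1 = ab(up["gamma0"], up["alpha_prime"])
            var_a += ((a1 - a0) / h * s) ** 2
            var_b += ((b1 - b0) / h * s) ** 2
        stderr["alpha"] = math.sqrt(var_a)
        stderr["beta"] = math.sqrt(var_b)

    def _covariance_stderr(self, values: dict[str, float]) -> dict[str, float]:
        """Residual-based standard errors at the optimum.

        Finite-difference Jacobian J of the residual vector; the covariance
        is s^2 (J^T J)^-1 with s^2 the reduced sum of squares.  Singular
        directions (e.g. tilt azimuth at exactly zero tilt) produce large,
        honest uncertainties via the pseudo-inverse.
        """
        names = self._free_names()
        r0 = self._residual_vector(values)
        n, p = r0.size, len(names)
        J = np.empty((n, p))
        for j, name in enumerate(names):
            h = max(1e-6, 1e-6 * abs(values[name]))
            up = dict(values)
            up[name] = values[name] + h
            dn = dict(values)
            dn[name] = values[name] - h
            if name.startswith("N_"):
                dn[name] = max(dn[name], 0.0)
                h = (up[name] - dn[name]) / 2
            if name.startswith("w_mu_"):
                dn[name] = max(dn[name], W_MU_MIN / 2)
                h = (up[name] - dn[name]) / 2
            J[:, j] = (self._residual_vector(up) - self._residual_vector(dn)) / (2 * h)
        dof = max(n - p, 1)
        s2 = float(r0 @ r0) / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        return {name: float(math.sqrt(max(cov[j, j], 0.0)))
                for j, name in enumerate(names)}


@dataclass
class JointFitResult:
    """Estimates, uncertainties and diagnostics of a joint azimuthal fit."""

    model: JointAzimuthalModel
    params: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    n_points: int
    success: bool
    reflections_used: list[str]
    mode: str

    @property
    def orientation(self) -> Orientation:
        return Orientation(self.params["alpha"], self.params["beta"])

    def fibre_axis(self) -> np.ndarray:
        """Unit fibre direction (L3 mode only)."""
        if self.mode != "L3_delta":
            raise ValueError("a single fibre axis exists only in L3_delta mode")
        return self.model.fibre_axis_from_params(self.params)

    def decomposition(self) -> TiltDecomposition:
        """Unambiguous (gamma, alpha') decomposition of the fitted fibre axis."""
        return decompose_orientation(self.fibre_axis())

    def to_record(self) -> dict:
        """Flat JSON-serializable record of the fit."""
        rec = {
            "schema_version": 1,
            "mode": self.mode,
            "success": self.success,
            "residual_norm": self.residual_norm,
            "n_points": self.n_points,
            "reflections_used": list(self.reflections_used),
        }
        for k, v in self.params.items():
            rec[k] = v
            rec[k + "_stderr"] = self.stderr.get(k, math.nan)
        if self.mode == "L3_delta":
            try:
                td = self.decomposition()
                rec["gamma_decomp"] = td.gamma
                rec["alpha_prime"] = td.alpha_prime
            except ValueError:
                pass
        return rec

    def summary(self) -> str:
        """Human-readable parameter table (angles in degrees)."""
        lines = [
            "Joint azimuthal fit",
            "===================",
            f"mode:               {self.mode}",
            f"reflections used:   {', '.join(self.reflections_used)}",
            f"converged:          {self.success}",
            f"residual norm:      {self.residual_norm:.6g} ({self.n_points} points)",
            "",
            f"{'parameter':<14}{'value':>14}{'std err':>14}",
            "-" * 42,
        ]
        for k in sorted(self.params):
            v, e = self.params[k], self.stderr.get(k, math.nan)
            if k.startswith(("alpha", "beta", "gamma", "w_mu")):
                lines.append(
                    f"{k:<14}{math.degrees(v):>13.3f}°{math.degrees(e):>13.3f}°"
                )
            else:
                lines.append(f"{k:<14}{v:>14.5g}{e:>14.5g}")
        if self.mode == "L3_delta":
            try:
                td = self.decomposition()
                lines += [
                    "",
                    f"(gamma, alpha') decomposition: "
                    f"({math.degrees(td.gamma):.3f}°, "
                    f"{math.degrees(td.alpha_prime):.3f}°)",
                ]
            except ValueError:
                pass
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data (points) and fitted model (lines) per reflection."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label in self.reflections_used:
            prof = self.model.profiles[label]
            fit = self.model.profile_model(label, self.params)
            ax.plot(prof.chi_deg[prof.valid], prof.intensity[prof.valid],
                    ".", ms=3, label=f"{label} data")
            ax.plot(prof.chi_deg, fit, "-", label=f"{label} fit")
        ax.set_xlabel("azimuth chi (deg)")
        ax.set_ylabel("intensity (counts)")
        ax.legend()
        return ax


@dataclass
class ScanResult:
    """Per-point joint and radial fits over a raster grid plus maps.

    maps keys: alpha, beta, gamma0 (L3), w_mu_110, d_110, sigma_110, I_110;
    all 2D arrays shaped like the scan grid with NaN at failed points.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    maps: dict[str, np.ndarray]
    ok: np.ndarray
    fit_results: list
    radial_results: list

    @property
    def shape(self) -> tuple[int, int]:
        return self.ok.shape


def fit_scan(
    frames: list[DetectorImage],
    geometry: DetectorGeometry,
    cell: UnitCell,
    config: JointFitConfig | None = None,
    reflections: dict[str, ReflectionSpec] | None = None,
    scan_shape: tuple[int, int] | None = None,
    step_um: tuple[float, float] = (7.0, 3.0),
    primary: str = "110",
    n_chi_bins: int = 360,
    subtract_background: bool = False,
) -> ScanResult:
    """Reduce and fit every frame of a raster scan.

    Per point: azimuthal profiles for each configured reflection (with
    optional ring background subtraction), a joint azimuthal fit, and a
    radial multi-peak fit of the primary reflection.  Failed points are
    flagged in ``ok`` and hold NaN in the maps — never interpolated.

    ``scan_shape`` is (rows, cols); defaults to a single row.
    """
    config = config or JointFitConfig(mode="L3_delta")
    reflections = reflections or CHITIN_REFLECTIONS
    n = len(frames)
    if scan_shape is None:
        scan_shape = (1, n)
    rows, cols = scan_shape
    if rows * cols != n:
        raise ValueError("scan_shape does not match number of frames")
    geoms = {lab: ring_geometry(cell, spec) for lab, spec in reflections.items()}

    keys = ["alpha", "beta", f"w_mu_{primary}", f"d_{primary}",
            f"sigma_{primary}", f"I_{primary}"]
    if config.mode == "L3_delta":
        keys[2:2] = ["gamma0", "alpha_prime"]
    maps = {k: np.full(scan_shape, np.nan) for k in keys}
    ok = np.zeros(scan_shape, dtype=bool)
    fit_results: list = []
    radial_results: list = []
    beam = BeamGeometry(geometry.wavelength_nm)

    for idx, frame in enumerate(frames):
        r, c = divmod(idx, cols)
        fit_res = None
        rad_res = None
        try:
            profiles = {}
            for lab, spec in reflections.items():
                if spec.radial_band is None:
                    continue
                if subtract_background:
                    profiles[lab] = ring_background_subtract(
                        frame, geometry, spec.radial_band,
                        inner_only=(lab == "002"), n_chi_bins=n_chi_bins,
                    )
                else:
                    profiles[lab] = azimuthal_integrate(
                        frame, geometry, spec.radial_band, n_chi_bins=n_chi_bins
                    )
            model = JointAzimuthalModel(profiles, geoms, beam, config)
            fit_res = model.fit()
            rad = radial_integrate(frame, geometry)
            rad_res = fit_radial_peaks(rad, reflections[primary], cell)
            maps["alpha"][r, c] = fit_res.params["alpha"]
            maps["beta"][r, c] = fit_res.params["beta"]
            if config.mode == "L3_delta":
                maps["gamma0"][r, c] = fit_res.params["gamma0"]
                maps["alpha_prime"][r, c] = fit_res.params["alpha_prime"]
            wkey = f"w_mu_{primary}"
            if wkey in fit_res.params:
                maps[wkey][r, c] = fit_res.params[wkey]
            maps[f"d_{primary}"][r, c] = rad_res.d_spacing
            maps[f"sigma_{primary}"][r, c] = rad_res.sigma
            maps[f"I_{primary}"][r, c] = rad_res.area
            ok[r, c] = fit_res.success
        except (ValueError, NoPeakError):
            pass
        fit_results.append(fit_res)
        radial_results.append(rad_res)

    x = np.arange(cols) * step_um[0]
    y = np.arange(rows) * step_um[1]
    return ScanResult(
        x_um=x, y_um=y, maps=maps, ok=ok,
        fit_results=fit_results, radial_results=radial_results,
    )


def export_orientation_glyphs(
    scan: ScanResult,
    elongation_scale: float = math.radians(5.0),
    primary: str = "110",
) -> pd.DataFrame:
    """Per-point glyph table: position, unit fibre direction and elongation.

    Elongation = elongation_scale / w_mu(primary): well-aligned voxels map
    to elongated ellipsoids, misaligned ones to more spherical glyphs.
    Unfitted points are omitted.  The CSV written from this table is
    consumable by generic 3D glyph viewers.
    """
    rows = []
    nrow, ncol = scan.shape
    for r in range(nrow):
        for c in range(ncol):
            if not scan.ok[r, c]:
                continue
            fr = scan.fit_results[r * ncol + c]
            if fr is not None and fr.mode == "L3_delta":
                n = fr.fibre_axis()
            else:
                # L1: the glyph direction is the tilted array normal
                alpha = scan.maps["alpha"][r, c]
                beta = scan.maps["beta"][r, c]
                from .forward import rot_x, rot_y

                n = rot_x(alpha) @ rot_y(beta) @ np.array([0.0, 0.0, 1.0])
            w = scan.maps[f"w_mu_{primary}"][r, c]
            rows.append(
                {
                    "x_um": float(scan.x_um[c]),
                    "y_um": float(scan.y_um[r]),
                    "nx": float(n[0]),
                    "ny": float(n[1]),
                    "nz": float(n[2]),
                    "elongation": float(elongation_scale / w)
                    if np.isfinite(w) and w > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
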