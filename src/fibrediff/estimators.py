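"""Azimuthal peak summaries and their inversion to tilt/dispersion estimates.

For a single fibre the azimuthal profile of each reflection class carries a
signature of the out-of-plane tilt alpha and the angular dispersion w_mu:

* axial (00l): two peaks at 90/270 deg whose FWHM and upper/lower intensity
  ratio I(90)/I(270) change with alpha (the ratio grows monotonically);
* equatorial (hk0): two equal-height peaks whose separation deviates from
  180 deg with tilt (Ewald-sphere curvature);
* general (hkl): split peaks near alpha = 0 that merge as the tilt grows.

``summarize_profile`` measures these features on a sampled profile;
``predict_summary`` computes them semi-analytically from the closed-form
single-fibre intensity by 1D extremum/half-height root-finding; a lookup
table over (alpha, w_mu) built from ``predict_summary`` can be inverted for
quick initial estimates before full nonlinear fitting.

The (gamma, alpha') decomposition expresses any non-beam-parallel fibre
direction as an in-plane rotation about the beam followed by a single
out-of-plane tilt; it is the unambiguous counterpart of the (alpha, beta)
parameterization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator

from .forward import (
    BeamGeometry,
    Orientation,
    PeakShape,
    ewald_vector,
    fibre_direction,
    single_fibril_intensity,
)
from .lattice import ReflectionGeometry
from .profiles import AzimuthalProfile

__all__ = [
    "NoPeakError",
    "ExtrapolationError",
    "PeakSummary",
    "TiltDecomposition",
    "summarize_profile",
    "predict_summary",
    "LookupTable",
    "build_lookup",
    "invert_summary",
    "InversionResult",
    "decompose_orientation",
    "compose_orientation",
    "alpha_beta_from_direction",
    "classify_reflection",
]

TWO_PI = 2.0 * math.pi


class NoPeakError(ValueError):
    """Raised when a profile has fewer resolvable peaks than required."""


class ExtrapolationError(ValueError):
    """Raised when observed features fall outside the lookup-table hull."""


@dataclass
class PeakSummary:
    """Peak features of an azimuthal profile.

    positions are sorted ascending in [0, 2pi); hwhm_left/right are the
    angular distances from each peak to its half-height crossings (NaN when
    a crossing is unreachable, e.g. masked bins); split marks peaks made of
    two sub-maxima separated by an above-half-height local minimum within
    one quadrant.  ratio_upper_lower is the height of the peak nearest the
    'upper' reference azimuth divided by that nearest the 'lower' one
    (90/270 deg for axial and general reflections, 180/0 deg for
    equatorial).
    """

    positions: np.ndarray
    heights: np.ndarray
    hwhm_left: np.ndarray
    hwhm_right: np.ndarray
    split: np.ndarray
    ratio_upper_lower: float
    upper_chi: float = math.pi / 2
    lower_chi: float = 3 * math.pi / 2

    @property
    def fwhm(self) -> np.ndarray:
        return self.hwhm_left + self.hwhm_right

    def peak_nearest(self, chi: float) -> int:
        """Index of the peak circularly nearest azimuth chi."""
        d = np.abs(np.remainder(self.positions - chi + math.pi, TWO_PI) - math.pi)
        return int(np.argmin(d))

    def separation(self) -> float:
        """Circular separation between the two main peaks (two-peak profiles)."""
        if len(self.positions) < 2:
            raise NoPeakError("separation requires two peaks")
        i = np.argsort(self.heights)[-2:]
        p = np.sort(self.positions[i])
        return float(p[1] - p[0])


def _circ_delta(a: float, b: float) -> float:
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    return float(np.remainder(a - b + math.pi, TWO_PI) - math.pi)


def summarize_profile(
    profile: AzimuthalProfile,
    upper_chi: float = math.pi / 2,
    lower_chi: float = 3 * math.pi / 2,
    min_rel_height: float = 0.5,
    refine_window: int = 1,
) -> PeakSummary:
    """Locate peaks above ``min_rel_height`` of the global maximum.

    Local maxima are refined by parabolic interpolation (3-point for the
    default ``refine_window=1``; a least-squares quadratic over +-window
    bins for noisy counting data, which averages Poisson jitter at the
    peak top); half-height crossings by linear interpolation.  Sub-maxima
    within one quadrant of each other whose intervening minimum stays
    above half of the weaker one are merged into a single peak flagged as
    split.
    """
    chi = profile.chi
    I = np.where(profile.valid, profile.intensity, np.nan)
    nb = len(chi)
    if nb < 8 or not profile.valid.any():
        raise NoPeakError("profile too short or fully masked")
    M = np.nanmax(I)
    if not (M > 0):
        raise NoPeakError("profile has no positive intensity")
    thresh = min_rel_height * M

    prev = np.roll(I, 1)
    nxt = np.roll(I, -1)
    with np.errstate(invalid="ignore"):
        is_max = (I >= prev) & (I >= nxt) & (I > thresh)
    is_max &= np.isfinite(prev) & np.isfinite(nxt)
    cand = np.flatnonzero(is_max)
    # collapse plateau runs (circular): keep first of each run
    cand = [i for i in cand if not ((i - 1) % nb in set(cand) and I[i] == I[(i - 1) % nb])]
    if len(cand) < 1:
        raise NoPeakError("no peaks above half of the global maximum")

    step = chi[1] - chi[0]

    def refine(i: int) -> tuple[float, float]:
        k = max(1, int(refine_window))
        idx = np.arange(i - k, i + k + 1)
        y = I[idx % nb]
        if not np.all(np.isfinite(y)):
            return float(chi[i]), float(I[i])
        if k == 1:
            y0, y1, y2 = y
            denom = y0 - 2 * y1 + y2
            if denom >= 0:
                return float(chi[i]), float(y1)
            off = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            return float(chi[i] + off * step), float(y1 - 0.25 * (y0 - y2) * off)
        x = (idx - i).astype(float)
        a, b, c = np.polyfit(x, y, 2)
        if a >= 0:
            return float(chi[i]), float(I[i])
        off = float(np.clip(-b / (2 * a), -k, k))
        return float(chi[i] + off * step), float(c - b * b / (4 * a))

    refined = [refine(i) for i in cand]

    def min_between(i: int, j: int) -> float:
        """Minimum intensity along the short circular arc from bin i to j."""
        if (j - i) % nb > nb // 2:
            i, j = j, i
        if i <= j:
            seg = I[i : j + 1]
        else:
            seg = np.concatenate([I[i:], I[: j + 1]])
        return float(np.nanmin(seg)) if np.isfinite(seg).any() else np.nan

    # cluster circularly-adjacent sub-maxima into split peaks
    order = np.argsort([r[0] for r in refined])
    idx = [cand[k] for k in order]
    pos = [refined[k][0] for k in order]
    hgt = [refined[k][1] for k in order]
    m = len(idx)
    link = [False] * m  # link[k]: sub-max k joined with k+1 (circular)
    for k in range(m):
        k2 = (k + 1) % m
        sep = (pos[k2] - pos[k]) % TWO_PI
        if 0 < sep < math.pi / 2 and m > 1:
            mb = min_between(idx[k], idx[k2])
            # sub-maxima of one split peak: the dip between them stays
            # above half of the weaker sub-maximum
            if np.isfinite(mb) and mb > 0.5 * min(hgt[k], hgt[k2]):
                link[k] = True
    # build clusters from links
    clusters: list[list[int]] = []
    used = [False] * m
    for k in range(m):
        if used[k]:
            continue
        grp = [k]
        used[k] = True
        j = k
        while link[j] and not used[(j + 1) % m]:
            j = (j + 1) % m
            grp.append(j)
            used[j] = True
        clusters.append(grp)
    # circular wrap: merge first and last cluster if linked
    if len(clusters) > 1 and link[clusters[-1][-1]]:
        clusters[0] = clusters[-1] + clusters[0]
        clusters.pop()

    peaks = []
    for grp in clusters:
        # rank sub-maxima by raw counts: fitted vertex heights can be
        # unreliable on shoulder bins
        best = max(grp, key=lambda k: I[idx[k]])
        peaks.append(
            {
                "pos": pos[best],
                "height": hgt[best],
                "split": len(grp) > 1,
                "index": idx[best],
            }
        )
    if len(peaks) < 2:
        raise NoPeakError(
            f"only {len(peaks)} resolvable peak(s) above half maximum"
        )

    def half_crossing(i0: int, height: float, direction: int) -> float:
        """Angular distance from bin i0 to the half-height crossing."""
        half = 0.5 * height
        travelled = 0.0
        i = i0
        step = chi[1] - chi[0]
        for _ in range(nb):
            j = (i + direction) % nb
            if not np.isfinite(I[j]):
                return np.nan
            travelled += step
            if I[j] < half:
                # linear interpolation between i and j
                frac = (I[i] - half) / (I[i] - I[j])
                return travelled - step * (1.0 - frac)
            i = j
        return np.nan

    res_pos, res_h, res_l, res_r, res_s = [], [], [], [], []
    for p in peaks:
        res_pos.append(p["pos"] % TWO_PI)
        res_h.append(p["height"])
        res_l.append(half_crossing(p["index"], p["height"], -1))
        res_r.append(half_crossing(p["index"], p["height"], +1))
        res_s.append(p["split"])
    order = np.argsort(res_pos)
    positions = np.array(res_pos)[order]
    heights = np.array(res_h)[order]
    hw_l = np.array(res_l)[order]
    hw_r = np.array(res_r)[order]
    split = np.array(res_s, dtype=bool)[order]

    du = [abs(_circ_delta(p, upper_chi)) for p in positions]
    dl = [abs(_circ_delta(p, lower_chi)) for p in positions]
    ratio = float(heights[int(np.argmin(du))] / heights[int(np.argmin(dl))])
    return PeakSummary(
        positions=positions,
        heights=heights,
        hwhm_left=hw_l,
        hwhm_right=hw_r,
        split=split,
        ratio_upper_lower=ratio,
        upper_chi=upper_chi,
        lower_chi=lower_chi,
    )


def classify_reflection(mu: float, tol: float = 1e-6) -> str:
    """'00l' for mu ~ 0, 'hk0' for mu ~ pi/2, else 'hkl'."""
    if abs(mu) < tol:
        return "00l"
    if abs(mu - math.pi / 2) < tol:
        return "hk0"
    return "hkl"


_CLASS_REFS = {
    "00l": (math.pi / 2, 3 * math.pi / 2),
    "hkl": (math.pi / 2, 3 * math.pi / 2),
    "hk0": (math.pi, 0.0),
}


def _single_fibre_I(
    mu: float, alpha: float, w_mu: float, beam: BeamGeometry, q0: float
):
    """Continuous azimuthal intensity of a vertical single fibre tilted by alpha."""
    geom = ReflectionGeometry(mu=mu, q0_nominal=q0)
    shape = PeakShape(amplitude=1.0, w_mu=w_mu, q0=q0, dq=1.0)
    n = fibre_direction(math.pi / 2, Orientation(alpha, 0.0))

    def f(chi):
        Q = ewald_vector(q0, np.asarray(chi, dtype=float), beam)
        return single_fibril_intensity(Q, n, geom, shape)

    return f


def predict_summary(
    reflection_class: str,
    mu: float,
    alpha: float,
    w_mu: float,
    beam: BeamGeometry,
    q0: float,
    coarse_step_deg: float = 0.05,
) -> PeakSummary:
    """Model-implied peak summary for a single vertical fibre tilted by alpha.

    Semi-analytic route: the continuous single-fibre intensity I(chi) at
    q = q0 is scanned on a fine grid to bracket features, then each peak
    position is polished by bounded scalar minimization and each half-height
    crossing by Brent root-finding.  Agrees with
    ``summarize_profile(azimuthal_profile(...))`` to well under 0.2 deg in
    positions and 2% in ratios.
    """
    cls = classify_reflection(mu)
    if cls != reflection_class:
        raise ValueError(
            f"reflection_class {reflection_class!r} inconsistent with mu={mu!r}"
        )
    if abs(alpha) >= math.pi / 2:
        raise ValueError("require |alpha| < pi/2")
    f = _single_fibre_I(mu, alpha, w_mu, beam, q0)
    step = math.radians(coarse_step_deg)
    chi = np.arange(0.0, TWO_PI, step)
    upper, lower = _CLASS_REFS[reflection_class]
    base = summarize_profile(
        AzimuthalProfile(chi=chi, intensity=f(chi)),
        upper_chi=upper, lower_chi=lower,
        # noiseless model profile: keep the suppressed lower peak visible
        # even at large intensity ratios
        min_rel_height=0.01,
    )

    # polish each peak position and height on the continuous intensity
    pos, hgt = [], []
    for p in base.positions:
        r = optimize.minimize_scalar(
            lambda x: -float(f(x)), bounds=(p - 2 * step, p + 2 * step),
            method="bounded", options={"xatol": 1e-10},
        )
        pos.append(float(r.x) % TWO_PI)
        hgt.append(-float(r.fun))

    def crossing(p: float, h: float, sgn: int, guess: float) -> float:
        if not np.isfinite(guess):
            return np.nan
        half = 0.5 * h
        g = lambda x: float(f(x)) - half
        a = p + sgn * max(guess - 2 * step, 0.0)
        b = p + sgn * (guess + 2 * step)
        lo, hi = (a, b) if a < b else (b, a)
        try:
            root = optimize.brentq(g, lo, hi, xtol=1e-10)
        except ValueError:
            return guess
        return abs(root - p)

    hw_l = [
        crossing(p, h, -1, g)
        for p, h, g in zip(pos, hgt, base.hwhm_left)
    ]
    hw_r = [
        crossing(p, h, +1, g)
        for p, h, g in zip(pos, hgt, base.hwhm_right)
    ]
    order = np.argsort(pos)
    positions = np.array(pos)[order]
    heights = np.array(hgt)[order]
    du = [abs(_circ_delta(p, upper)) for p in positions]
    dl = [abs(_circ_delta(p, lower)) for p in positions]
    ratio = float(heights[int(np.argmin(du))] / heights[int(np.argmin(dl))])
    return PeakSummary(
        positions=positions,
        heights=heights,
        hwhm_left=np.array(hw_l)[order],
        hwhm_right=np.array(hw_r)[order],
        split=base.split[order] if len(base.split) == len(order) else base.split,
        ratio_upper_lower=ratio,
        upper_chi=upper,
        lower_chi=lower,
    )


def _summary_features(summary: PeakSummary) -> dict[str, float]:
    """Scalar features used by lookup tables: FWHM of the upper peak, the
    upper/lower intensity ratio and the deviation of the two-peak
    separation from 180 deg (radians)."""
    iu = summary.peak_nearest(summary.upper_chi)
    fwhm = float(summary.hwhm_left[iu] + summary.hwhm_right[iu])
    sep_dev = summary.separation() - math.pi
    return {
        "fwhm": fwhm,
        "ratio": summary.ratio_upper_lower,
        "sep_dev": float(sep_dev),
    }


_DEFAULT_FEATURES = {
    "00l": ("fwhm", "ratio"),
    "hk0": ("fwhm", "sep_dev"),
    "hkl": ("fwhm", "ratio"),
}

FEATURE_NAMES = ("fwhm", "ratio", "sep_dev")


@dataclass
class LookupTable:
    """predict_summary features tabulated over an (alpha, w_mu) grid."""

    reflection_class: str
    mu: float
    q0: float
    wavelength_nm: float
    alpha_grid: np.ndarray
    wmu_grid: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        """Long-format CSV plus a JSON sidecar with the grid metadata."""
        aa, ww = np.meshgrid(self.alpha_grid, self.wmu_grid, indexing="ij")
        data = {"alpha": aa.ravel(), "w_mu": ww.ravel()}
        for name in FEATURE_NAMES:
            data[name] = self.features[name].ravel()
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
        meta = {
            "reflection_class": self.reflection_class,
            "mu": self.mu,
            "q0": self.q0,
            "wavelength_nm": self.wavelength_nm,
            "alpha_grid": list(map(float, self.alpha_grid)),
            "wmu_grid": list(map(float, self.wmu_grid)),
            "angle_unit": "radians",
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path: str) -> "LookupTable":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        df = pd.read_csv(path)
        na, nw = len(meta["alpha_grid"]), len(meta["wmu_grid"])
        feats = {
            name: df[name].to_numpy().reshape(na, nw) for name in FEATURE_NAMES
        }
        return cls(
            reflection_class=meta["reflection_class"],
            mu=meta["mu"],
            q0=meta["q0"],
            wavelength_nm=meta["wavelength_nm"],
            alpha_grid=np.array(meta["alpha_grid"]),
            wmu_grid=np.array(meta["wmu_grid"]),
            features=feats,
        )


def build_lookup(
    reflection_class: str,
    mu: float,
    alpha_grid: np.ndarray,
    wmu_grid: np.ndarray,
    beam: BeamGeometry,
    q0: float,
) -> LookupTable:
    """Tabulate predict_summary features over strictly increasing grids."""
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    wmu_grid = np.asarray(wmu_grid, dtype=float)
    if alpha_grid.size == 0 or wmu_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(alpha_grid) <= 0) or np.any(np.diff(wmu_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    feats = {name: np.empty((len(alpha_grid), len(wmu_grid))) for name in FEATURE_NAMES}
    for i, a in enumerate(alpha_grid):
        for j, w in enumerate(wmu_grid):
            s = predict_summary(reflection_class, mu, a, w, beam, q0)
            fv = _summary_features(s)
            for name in FEATURE_NAMES:
                feats[name][i, j] = fv[name]
    return LookupTable(
        reflection_class=reflection_class,
        mu=mu,
        q0=q0,
        wavelength_nm=beam.wavelength_nm,
        alpha_grid=alpha_grid,
        wmu_grid=wmu_grid,
        features=feats,
    )


@dataclass(frozen=True)
class InversionResult:
    alpha: float
    w_mu: float
    alpha_uncertainty: float
    wmu_uncertainty: float


def invert_summary(
    summary: PeakSummary,
    table: LookupTable,
    feature_pair: tuple[str, str] | None = None,
) -> InversionResult:
    """Invert peak features to (alpha, w_mu) by nearest-node lookup plus
    local interpolated refinement.

    Features outside the tabulated range raise :class:`ExtrapolationError`.
    The reported uncertainties are half the local grid spacing.
    """
    if feature_pair is None:
        feature_pair = _DEFAULT_FEATURES[table.reflection_class]
    obs = _summary_features(summary)
    scales = {}
    for name in feature_pair:
        col = table.features[name]
        lo, hi = float(np.nanmin(col)), float(np.nanmax(col))
        span = hi - lo
        if not (lo - 1e-12 <= obs[name] <= hi + 1e-12):
            raise ExtrapolationError(
                f"feature {name}={obs[name]:.4g} outside table range [{lo:.4g}, {hi:.4g}]"
            )
        scales[name] = span if span > 0 else 1.0

    # nearest node in normalized feature space
    cost = np.zeros_like(table.features[feature_pair[0]])
    for name in feature_pair:
        cost += ((table.features[name] - obs[name]) / scales[name]) ** 2
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    a0, w0 = table.alpha_grid[i], table.wmu_grid[j]

    interp = {
        name: RegularGridInterpolator(
            (table.alpha_grid, table.wmu_grid), table.features[name],
            bounds_error=False, fill_value=None,
        )
        for name in feature_pair
    }
    lo = (table.alpha_grid[0], table.wmu_grid[0])
    hi = (table.alpha_grid[-1], table.wmu_grid[-1])

    def resid(x):
        pt = np.clip(np.asarray(x, dtype=float), lo, hi).reshape(1, 2)
        return [
            (float(interp[name](pt)[0]) - obs[name]) / scales[name]
            for name in feature_pair
        ]

    sol = optimize.least_squares(resid, x0=[a0, w0], bounds=(lo, hi), xtol=1e-12)
    da = 0.5 * float(np.max(np.diff(table.alpha_grid))) if len(table.alpha_grid) > 1 else 0.0
    dw = 0.5 * float(np.max(np.diff(table.wmu_grid))) if len(table.wmu_grid) > 1 else 0.0
    return InversionResult(
        alpha=float(sol.x[0]), w_mu=float(sol.x[1]),
        alpha_uncertainty=da, wmu_uncertainty=dw,
    )


@dataclass(frozen=True)
class TiltDecomposition:
    """(gamma, alpha'): rotate about the beam by gamma so the fibre
    projection is vertical, then tilt out of plane by alpha'.
    gamma in (-pi/2, pi/2], alpha' in [-pi/2, pi/2]."""

    gamma: float
    alpha_prime: float


def compose_orientation(td: TiltDecomposition) -> np.ndarray:
    """Unit fibre direction n = R_z(gamma) (0, cos a', sin a')."""
    return rot_z_vec(td.gamma, td.alpha_prime)


def rot_z_vec(gamma: float, alpha_prime: float) -> np.ndarray:
    ca, sa = math.cos(alpha_prime), math.sin(alpha_prime)
    cg, sg = math.cos(gamma), math.sin(gamma)
    return np.array([-sg * ca, cg * ca, sa])


def decompose_orientation(n: np.ndarray, tol: float = 1e-8) -> TiltDecomposition:
    """Decompose a unit fibre direction into (gamma, alpha').

    Fibres are axes: n and -n are the same fibre, and the representative
    with non-negative y projection (alpha' >= 0 on the y = 0 boundary) is
    used, so compose(decompose(n)) reproduces n up to this sign.  A
    direction parallel to the beam has undefined gamma and is refused.
    """
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    rho = math.hypot(n[0], n[1])
    if rho < tol:
        raise ValueError("gamma undefined for a beam-parallel fibre direction")
    if n[1] < 0 or (n[1] == 0 and n[0] > 0):
        n = -n
    gamma = -math.atan2(n[0], n[1])
    alpha_prime = math.asin(max(-1.0, min(1.0, n[2])))
    return TiltDecomposition(gamma=gamma, alpha_prime=alpha_prime)


def alpha_beta_from_direction(n: np.ndarray, gamma: float) -> Orientation:
    """Solve fibre_direction(gamma, Orientation(alpha, beta)) = n for the
    tilt pair (alpha, beta) at a given in-plane angle gamma.

    Uses the closed-form component equations with a sign trial on sin(beta);
    falls back to least squares in the near-degenerate |cos gamma| -> 0
    limit (where beta is unidentifiable and is set to 0).
    """
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    cg, sg = math.cos(gamma), math.sin(gamma)
    if abs(cg) < 1e-9:
        # fibre vertical in its own frame; beta acts about the fibre axis
        sign = 1.0 if sg > 0 else -1.0
        return Orientation(alpha=math.atan2(sign * n[2], sign * n[1]), beta=0.0)
    cb = n[0] / cg
    if abs(cb) > 1.0 + 1e-9:
        raise ValueError("no (alpha, beta) solution for this direction/gamma")
    cb = max(-1.0, min(1.0, cb))
    best = None
    for sb in (math.sqrt(1 - cb * cb), -math.sqrt(1 - cb * cb)):
        u = sb * cg
        det = sg * sg + u * u
        if det < 1e-14:
            continue
        ca = (sg * n[1] - u * n[2]) / det
        sa = (sg * n[2] + u * n[1]) / det
        err = abs(ca * ca + sa * sa - 1.0)
        if best is None or err < best[0]:
            best = (err, math.atan2(sa, ca), math.atan2(sb, cb))
    if best is None or best[0] > 1e-6:
        sol = optimize.least_squares(
            lambda x: fibre_direction(gamma, Orientation(x[0], x[1])) - n,
            x0=[0.0, 0.0],
        )
        return Orientation(alpha=float(sol.x[0]), beta=float(sol.x[1]))
    return Orientation(alpha=best[1], beta=best[2])
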