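# Methods

## Scope and coordinate conventions

The package models wide-angle diffraction from materials whose basic
scattering unit is a nanofibril with *fibre symmetry*: crystallites are
rotationally averaged about the fibril long axis (the crystallographic c
axis), so each reciprocal node (hkl) becomes a ring around that axis.  The
lab frame is right-handed with x horizontal and y vertical on the
detector; the beam propagates along −z, so the scattering vector
**Q** = **k**_out − **k**_in has a positive z component,
**Q**(q, χ) = (q cosθ cosχ, q cosθ sinχ, q sinθ) with sinθ = qλ/4π.  With
this handedness a positive α tilt (fibre top moving toward +z, i.e. away
from the detector) strengthens the upper (χ = 90°) axial peak — the sense
in which tilt signatures are conventionally read in fibre-diffraction
work.  The azimuth χ is counted counterclockwise from +x.

Orientations are handled in two equivalent parameterizations:

* **(α, β)** — tilts about the lab x and y axes applied to a fibre (or
  fibre-array plane) initially in the x–y plane:
  n̂ = R_x(α)·R_y(β)·(cos γ, sin γ, 0).
* **(γ, α′)** — rotate about the beam by γ so the fibre projection is
  vertical, then tilt out of plane by α′: n̂ = R_z(γ)·(0, cos α′, sin α′).

The second is unambiguous (2 parameters for the 2 degrees of freedom of an
axis) and is what the single-direction (L3) fits use internally; (α, β) is
derived from it for reporting.  Near β = 0 the map (γ, α′) → (α, β) is
ill-conditioned — a tiny change of γ moves β by degrees while the physical
axis barely moves — so the (γ₀, α′) values are the stable quantities to
read from L3 results.  Fibres are axes (n ≡ −n, γ has period π); the
decomposition picks the representative with non-negative y projection.

## Intensity model

Single fibril, reflection with opening angle μ and nominal radius q₀:

I(**Q**) = N·[L(φ−(π/2−μ); w_μ) + L(φ+(π/2−μ); w_μ)]·exp(−(|Q|−q₀)²/(2·dq²))

with φ = arcsin(Q̂·n̂) and L(x; w) = w²/(x²+w²).  Choices worth noting:

* The band profile is the **sum** of two unit-height Lorentzians at
  ±(π/2−μ) in latitude.  One expression covers axial (the two terms
  coincide in effect), equatorial (they coincide exactly, doubling the
  height — absorbed by the free amplitude N) and general reflections with
  their mirror ring at π−μ.  A Lorentzian rather than Gaussian band
  reproduces the long tails seen in real azimuthal profiles; it also means
  rings never vanish sharply — the axial reflection of a strongly tipped
  fibre retains ≈1% of its untilted peak through the tails.
* N absorbs structure factor, exposure and detector response; no
  polarization, absorption or Lorentz corrections are applied.
* The radial Gaussian is independent of the angular factor; its centre and
  width report lattice spacing (d = 2π/q₀) and microstrain heterogeneity.

A planar array integrates the single-fibril intensity over the in-plane
angle γ against a π-periodic density w(γ): `uniform` (1/π, full Bouligand
stack), `gaussian` (wrapped normal with centre γ₀ and width Δγ₀), or
`delta` (single direction, quadrature bypassed).

**Quadrature.**  The γ integral uses a uniform midpoint rule with 181
nodes on [0, π) by default.  For a periodic integrand the midpoint rule
converges spectrally, and — unlike Gauss–Legendre on the same interval —
its error is essentially χ-independent, which is what makes the untilted
uniform-stack profile flat to better than 10⁻⁶ (coefficient of variation).
Narrow Gaussian distributions are renormalized on the node set so no mass
is lost to undersampling; below Δγ₀ ≈ π/362 the delta branch is the
appropriate model.  The node count is configurable wherever the integral
appears.

## Reduction

Pixel → (q, χ) mapping assumes a flat detector normal to the beam
(detector tilt is not modelled; geometries provide distance, pixel size,
beam centre and module-gap layout — Pilatus P3-2M and Eiger 4M presets
ship with the package).  Azimuthal profiles are mean counts of valid
pixels per χ bin (default 1° bins) over a radial band; bins with under
50% live pixels (module gaps) are masked and never interpolated.  Ring
background subtraction averages two 0.2 nm⁻¹ rings placed 0.1 nm⁻¹ below
and above the band (the guard offset is a documented default; the reduction
protocol this follows leaves it unspecified) and supports an inner-ring-only
mode for reflections whose outer side is contaminated by a broad
neighbour; with a sloped background the inner-only mode leaves a known
positive bias which is left visible rather than hidden.  Radial profiles
are azimuthal means on 0.05 nm⁻¹ bins over 4.1–25.7 nm⁻¹.

Radial peaks are fitted as simultaneous Gaussians on a shared local linear
background: the primary reflection plus every configured neighbour whose
nominal q₀ falls within ±1.5 nm⁻¹.  Centres are bounded to ±2% of nominal
(pre-strain scale); widths to 0.02–0.6 nm⁻¹, the plausible microstrain
range — an unbounded neighbour otherwise drifts into a pseudo-background
role.  Excluding overlapping neighbours measurably biases the primary
centre, which is why they are co-fitted rather than masked.  Fit failures
return a flagged result, not an exception.

## Estimation and fitting

`summarize_profile` measures peak positions (parabolic refinement; a
least-squares quadratic over ±`refine_window` bins for counting-noise
data), half-height crossings by linear interpolation, a split flag for
sub-maxima within one quadrant whose dip stays above half the weaker one,
and the upper/lower intensity ratio (90°/270° for axial and general
reflections, 180°/0° for equatorial).

`predict_summary` is the semi-analytic counterpart: it scans the
closed-form single-fibre intensity on a fine grid, then polishes each
extremum by bounded scalar minimization and each half-height crossing by
Brent root-finding.  Tabulating its features over an (α, w_μ) grid gives a
lookup table that inverts observed features to initial estimates (nearest
node plus local interpolated refinement; features outside the tabulated
hull are refused rather than extrapolated).  Useful regimes: the axial
upper/lower ratio [w²+(θ+α)²]/[w²+(θ−α)²] is monotone in α only for
|α| < √(w_μ²+θ²) (≈7° for w_μ = 5° at 14 keV), so default grids stay in
the small-tilt window; the equatorial peak separation leaves 180°
monotonically with tilt (an Ewald-curvature effect) and carries the tilt
sign.

Joint fits share (α, β) — plus (γ₀, α′) in single-direction mode — across
the azimuthal profiles of all visible reflections and minimize unweighted
(optionally Poisson-weighted) squared residuals over valid bins by
Nelder–Mead simplex.  Residuals are normalized per reflection by peak
counts and the linear amplitudes are profiled out at every evaluation
(variable projection), which removes the worst scaling pathologies from
the simplex.  A reflection whose peak counts fall below 5% of the
equatorial reference is excluded from the residual and recorded — axial
rings genuinely leave the Ewald sphere beyond ~10–20° of tilt toward the
beam, and the equatorial-only fit must (and does) still converge there.
Parameter uncertainties come from a finite-difference Jacobian at the
optimum, cov = s²(JᵀJ)⁻¹ via pseudo-inverse: flat-profile directions (the
tilt azimuth of an untilted uniform stack, or w_μ(110) under a uniform
in-plane average) surface as honestly large standard errors rather than
spurious precision.

Raster scans apply reduce → joint fit → radial fit per frame, assemble
per-point maps (α, β, γ₀, α′, w_μ(110), d(110), σ(110), I(110)), flag
failed points without interpolation, and export a glyph table (position,
unit direction, elongation ∝ 1/w_μ) for generic 3D viewers.

## Synthetic data

The generator emulates the measurement conditions the model targets:
Bouligand stacks whose in-plane angle advances linearly with depth
(default 3°/µm so a 60 µm lamella sweeps the full π period, endocuticle
scale), constant stack tilt, elevated misalignment (default ×1.5 within
3 µm of lamella interfaces), beamline-like geometry presets (14 keV/296 mm
Pilatus P3-2M; 17 keV/166 mm Eiger 4M) or reduced-pixel variants for
speed, Poisson counting noise from one explicit seed, module gaps masked,
and an optional smooth radial polynomial background.  Default peak shapes
put the equatorial (110) brightest and broadest (w_μ = 8°) with axial
(002) and general (013) at 5°, amplitudes in the ratio 1000:600:400 and
dq = 0.35 nm⁻¹ — representative of hydrated chitin cuticle at these
energies.  Every generated artefact is accompanied by its ground-truth
table.

What the generator does **not** emulate: detector point-spread and
distortion, polarization/absorption corrections, mineral-phase
reflections, fluorescence, sample-thickness smearing of the probed depth,
and real inter-fibril disorder beyond the Lorentzian band + wrapped-normal
spread.  Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
every artefact of real beamline data.

## Default study conditions and problem sizes

Unit cell: the standard orthorhombic α-chitin literature cell a = 0.474,
b = 1.886, c = 1.032 nm (c along the fibril), which places the
(002)/(110)/(013) rings at 12.18/13.67/18.57 nm⁻¹, inside the shipped
radial integration bands (11.8–12.8, 12.8–15.5, 18.0–19.2 nm⁻¹).  Cells
and reflection sets are configuration, not constants; only orthorhombic
cells are supported.

Test and validation runs use scaled problem sizes chosen for sharp checks:
300×300-pixel detector variants for scan pipelines, a 1200×1200 variant
for render→integrate round trips (pixel discretization, not the model,
limits that agreement; it converges as pixels shrink), 20 noise seeds and
±30° truth tilts for L1 recovery, one 60 µm lamella at 6 µm steps for
pitch recovery, and 10⁵-point rings for brute-force oracles.

## Known limitations

* Orthorhombic cells only; detector assumed untilted.
* Azimuthal model profiles are evaluated at fixed q = q₀, not averaged
  over the radial band; for wide bands and tilted uniform stacks the
  band average differs from the fixed-q slice by a few percent (the
  render-then-integrate path is the band-averaging route).
* The (α, β) report of L3 fits inherits the near-degeneracy at β ≈ 0
  described above; uncertainty propagation to derived (α, β) neglects
  parameter correlations.
* Lookup-table inversion covers the single-fibre relations; planar-array
  summaries are seeded with the same relations and refined by the full
  fit, not inverted in closed form.
* Uncertainties are per-fit covariance estimates; across-frame scatter is
  the other convention in the field, and both are available when replicate
  frames exist.
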