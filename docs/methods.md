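# Methods

This note documents the models behind `vesselchip`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical decisions taken where the design was genuinely open.

## Channel geometry

The planform is a boustrophedon serpentine: straight limbs of rectangular
cross-section w × h = 200 µm × 50 µm joined by 180° circular bends. The
defaults (20 limbs of 9 mm, bend radius 0.3 mm) give a centerline path of
197.9 mm, matching the ~200 mm physical chip; only width, height and total
length are constrained by the device, so limb length, limb count and bend
radius are free choices made once to reproduce the overall morphology.

For serpentines of three or more limbs the bends overhang the limb ends, so
straight *leads* (bend radius + 2w long) extend the first and last limb to
the domain edge; leads carry path positions outside [0, L_total] and do not
count toward the nominal path length.

Two defects model the vascular-tumor pathologies:

* **clot** — a sharp-edged rectangular occlusion attached to one wall,
  blocking a fraction (default 0.5) of the width over an axial extent of
  200 µm (comparable to the channel width, like the observed mural
  aggregates). The sharp-edged rectangle is the simplest shape with the
  right constriction hydraulics.
* **wall gap** — a 20 µm-long aperture through the wall between adjacent
  limbs, the "leaky vessel" that produces bleeding into the neighbouring
  limb.

Rasterization is cell-centered at 5 µm pixels by default (4 µm for gap
scenes so the aperture spans ≥5 cells); each cell carries a wall-distance
map (Euclidean distance transform) and a centerline chart (path position s,
signed lateral offset d, unit tangent) used by the trajectory statistics.

## Flow model

At the working flow rates (0.5–1.0 µL·min⁻¹) the bulk speed is
~0.8–1.7 mm·s⁻¹ and Re ≈ 10⁻² — inertia is negligible. Because the channel
is shallow, the 3D Stokes equations are depth-averaged with an assumed
locally parabolic profile g(z), giving a 2D Stokes–Brinkman system

    (6/5) ∇·(η ∇u) − (12 η/h²) u − ∇p = 0,   ∇·u = 0.

The drag 12η/h² is the exact closure for a parabolic depth profile. The
6/5 factor on the in-plane viscous term is the Galerkin (profile-weighted)
projection, ∫g²dz / h = 6/5; with it the fully developed depth-averaged
profile matches the exact rectangular-duct series to ~1% at w/h = 4
(plain averaging, factor 1, errs by ~2.7%). This is the solver's validity
envelope: shallow, slowly varying planforms at Re ≪ 1; it cannot resolve
fully 3D features (corner vortices, out-of-plane recirculation).

Discretization: staggered (MAC) finite differences on the rasterized mask.
No-slip enters exactly on faces coinciding with walls and via mirror ghosts
for tangential components (second order on axis-aligned walls; bends are
staircase-approximated at the pixel scale). The inlet imposes the analytic
fully developed depth-averaged profile scaled so the *discrete* flux equals
Q exactly; the outlet pins the face pressure to zero. The coupled linear
system is solved by sparse LU; discrete continuity therefore holds to
machine precision, and the flux through every cross-section equals Q to
~10⁻¹² relative.

For Carreau fluids, the local viscosity is evaluated at a characteristic
shear rate combining in-plane strain with the dominant depthwise
contribution, γ̇ = √(γ̇²_plane + 12 |u|²/h²), and updated by Picard
iteration (relaxation 0.5, convergence when the largest relative viscosity
update is below 10⁻⁶, cap 200 iterations; typical runs converge in 20–30).
Setting η0 = η∞ reproduces the Newtonian solution to ≤10⁻¹⁰, so the
Newtonian path is the λ→0 limit of the same machinery.

Wall shear stress is reported by the thin-gap (plane-slit) estimate
τ = 6ηQ/(wh²), equivalent to η·∂v/∂z at the top/bottom walls where the
50 µm dimension controls the gradient; τ values are rounded to two decimals
(0.10 and 0.20 Pa at the two flow rates with a 1 cP medium), matching the
precision at which such estimates are meaningful. The slit formula is exact
for w/h → ∞ and ~13% high for the true duct at w/h = 4; both the formula
and the profile-gradient estimator are exposed so the approximation is
inspectable.

## Synthetic data

The generator emulates the chip's acquisitions: 0.75 µm tracer beads and
label-free RBC contrast imaged at 1 frame / 2 ms, 1 µm/pixel, 16-bit.

**Trajectories.** Beads advect along the depth-averaged velocity (midpoint
rule, 4 substeps per frame). Crowding by red cells is a Poisson collision
process: per frame step, k ~ Poisson(rate·Δt) collisions deflect the step
direction by a zero-mean Gaussian angle of SD σ_φ·√k. The collision rate
defaults to 50 s⁻¹ per hematocrit percent (2250 s⁻¹ at the adult default
Hct = 45%, i.e. several collisions per 2 ms frame — collision-dominated, as
in whole blood; Hct is a config knob since infant blood runs lower). σ_φ is
calibrated so the realized per-step mean |deflection| equals a target angle
(1.2° for the whole-blood condition — the experimentally measured scale,
used as a calibration anchor, not a prediction). Walls reflect (default) or
absorb; particles terminate at the outlet.

**Frames.** Beads render as Gaussian spots (σ = 1.5 px). RBC texture is
band-limited speckle (filtered white noise, 6 µm correlation length — the
red-cell scale) advected with the flow by semi-Lagrangian backtracing; it
gives PIV-trackable label-free contrast without simulating cells. Additive
Gaussian noise, then clipping to uint16. Rendering is a pure function of
(trajectories, optics, seed): reruns are byte-identical.

What the synthetic data deliberately *do not* contain: deformable or
discretely resolved red cells, margination and the cell-free layer's
feedback on rheology, coagulation kinetics, phase-contrast optics, depth of
field (all motion is at the mid-plane), Brownian motion of the 0.75 µm
beads (Péclet ≫ 1 at these speeds), and photobleaching. Passing tests
therefore validate the *measurement pipeline* (solver ↔ tracking ↔ PIV
consistency), not a cell-resolved model of blood.

## Tracking

Spot detection: local maxima above threshold, refined by background-
subtracted intensity centroids (≈0.2 px accuracy on rendered spots; peaks
closer than the separation merge into the brighter one). Linking: greedy
mutual-nearest-neighbour per frame pair with a displacement gate, ties
broken by distance then index — deterministic; ≥95% of links are correct on
non-crossing synthetic scenes.

Statistics follow the step definitions above. "Lateral" is measured
perpendicular to the *local* centerline tangent (bilinearly interpolated
from the grid chart), so bends do not inflate the scattering angle. The
interaction length uses tan rather than sin; at 1.2° the difference is
<0.03%, far below the quoted precision. φ̄ defaults to beads in the central
half of the width, mirroring how the experimental angles were measured.

A physical limitation worth stating: at Δt = 2 ms a bead moves ~1.7 µm
between frames, while centroid localization is good to ~0.15 px (0.15 µm).
Angles re-measured from *detected* positions are therefore noise-dominated
(several degrees of jitter against a 1.2° signal). The angle-recovery tests
accordingly run the estimator on generated trajectories; frame-based speed
measurements are unaffected (the noise is small relative to step length).

## Micro-PIV

Normalized cross-correlation template matching per interrogation window
(`skimage.feature.match_template`), peak → displacement, 3-point parabolic
subpixel fit per axis (skipped when the peak is exactly 1, i.e. an exact
integer shift). Defaults: 32 px window, 64 px search, 50% overlap — at
1 µm/px this puts ≥4 vectors across the 200 µm width while keeping ~5
independent speckle cells per window.

Quality control: (i) windows whose footprint overlaps solid are invalid —
they average moving and static texture and bias the peak; (ii) SNR is the
ratio of the first peak to the second *local maximum* of the correlation
surface (with smooth speckle the highest value outside an exclusion zone is
just the primary peak's shoulder, which would make the ratio useless);
default gate 1.5; (iii) vectors deviating from the 3×3 neighbourhood median
by >1 px are replaced by that median and flagged as interpolated, never
silently fabricated.

On frames rendered from a solved field, the PIV field closes the loop with
RMS residual <10% of the mean speed; residuals concentrate where the true
field varies within a window (near walls and clot edges) — the expected
window-averaging bias of correlation PIV. In the thrombus scene the PIV
constriction/open speed ratio comes out slightly above the simulated 2.0
(~2.1–2.2) because full-fluid windows in the narrowed lumen preferentially
sample the fast core; the two estimates agree within 15%.

## Problem sizes

The full 200 mm chip is represented geometrically but not solved; study
scenes are short sections that preserve the cross-section, clot fraction
and gap size, chosen so any scenario solves in seconds to a couple of
minutes on one core:

| scene      | geometry                               | pixels | fluid cells |
|------------|----------------------------------------|--------|-------------|
| straight   | one 2 mm limb                          | 5 µm   | 16 000      |
| baseline   | 2 × 0.8 mm limbs, bend r = 0.3 mm      | 5 µm   | 20 300      |
| thrombus   | 2 mm limb, clot at 1.4 mm              | 5 µm   | 15 200      |
| hemorrhage | 2 × 0.6 mm limbs, r = 0.25 mm, 20 µm gap | 4 µm | 25 300      |

All section-scale results (profiles, shear, constriction ratios, bend
asymmetry, gap crossflow) are local quantities independent of total chip
length; only absolute pressure drop scales with it.

## Known limitations

* Depth-averaging cannot represent out-of-plane secondary flows; the clot
  is a full-depth obstruction (no overhangs or partial-depth thrombi).
* Staircase walls limit bend-wall shear accuracy to the pixel scale; bend
  asymmetry is asserted qualitatively, not as a calibrated ratio.
* The scattering model is phenomenological (Poisson–Gaussian deflections
  calibrated to the measured angle scale); it reproduces the statistics of
  bead scattering, not its mechanics.
* The experimental bleed-through speed and capture fraction are
  model-dependent observables; the hemorrhage scene reproduces their
  qualitative signatures (reduced-speed crossflow through the gap), and no
  quantitative claim is made.
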