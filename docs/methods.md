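# Methods

`sclerapuff` simulates air-puff deformation imaging (APDI) of the rabbit
sclera with a nonlinear finite-element model, reproduces the model's
parametric studies (one-at-a-time sensitivity, random sampling), and
estimates the scleral material coefficient from apex-displacement-vs-IOP
data by bounded scalar inversion.  This note records the model, its
assumptions, the numerical choices, and what the synthetic studies do and
do not demonstrate.

## Geometry

The globe is a shell of revolution about the optical axis.  The exterior
is an ellipse with axial diameter AL (17–19 mm) and equatorial diameter
EL (18.4–19.6 mm); the interior ellipse is chosen with semi-axes
(AL/2 − 0.6, EL/2 − THK) so that the wall is exactly THK thick at the
equator (0.34–0.40 mm, the air-puff site) and 0.6 mm at the posterior
pole.  Along the meridian between those two points the thickness varies
smoothly and monotonically.  The cornea is a spherical cap of 0.4 mm
thickness whose junction with the sclera lies 120° from the optic nerve
and whose apex protrudes 1 mm beyond the exterior ellipse (total axial
extent AL + 1).  The cap is fitted through the junction ring and the apex
point; exact tangency to the ellipse is not imposed (a sphere cannot
satisfy apex offset, junction continuity and tangency simultaneously) and
the inner corneal surface blends linearly into the scleral inner surface
over one element ring at the limbus.  The model makes no attempt at
image-derived geometry, optic-nerve-head detail, or choroid/retina
layers.

Coordinates: origin at the globe centre, posterior pole on the negative
axial (x) axis, the equatorial "uppermost point" (0, EL/2, 0) on the
vertical y axis, z out of the sagittal plane.  The default mesh is a
quarter model (symmetry in the sagittal z = 0 and axial y = 0 planes); a
half model is available for off-plane load placements.

Meshing is structured: meridian × azimuth × radial layers of 20-node
serendipity hexahedra (quadratic displacement interpolation, the same
order as the solids used in the original model), collapsing into wedges
at the two poles.  Node density is clustered around the air-puff site
(Gaussian weighting of the arc-length density, σ = 2 mm).  The element
budget is a single `resolution` knob; at the default 5000 the volume of
the meshed shell matches the analytic ellipsoid-shell volume to well
under 1%, and there are always at least two element layers through the
wall.

## Material

The sclera is an isotropic, nearly incompressible one-term Ogden solid.
Under incompressible uniaxial tension the law reduces to

    σ(λ) = μ (λ^α − λ^(−α/2)),

with the curve-shape exponent fixed at α = 40 (steeply strain-stiffening,
as scleral tissue is) and the magnitude coefficient μ in MPa as the
biomechanical unknown (baseline 0.083 MPa; small-strain shear modulus
μα/2 ≈ 1.66 MPa).  Spatial grading is linear along the axial coordinate:
μ(x) = μ − (μ − μ_post)·x/x_f from the equator (x = 0) to the most
posterior scleral point (x = x_f), with μ_post/μ between 0.25 and 1.
Anterior of the equator the coefficient is constant at μ; the cornea
defaults to the same Ogden form with μ_cornea = μ (configurable — the
cornea is far from the puff site and weakly coupled to the outputs).
No fibre anisotropy, no viscoelasticity.

The 3D law derives from the strain energy
W = (μ/α)(J^(−α/3)·tr C^(α/2) − 3) + (κ/2)(J − 1)², using that for even
integer α the sum of principal-stretch powers Σλᵢ^α equals tr(C^(α/2)),
an integer matrix power of the right Cauchy–Green tensor.  Stress and
consistent tangent are therefore polynomial in C and fully analytic — no
eigendecomposition, no repeated-eigenvalue special cases.  The 3D path
consequently requires even integer α (the model fixes α = 40); the
uniaxial closed form accepts any α > 0.  Incompressibility is enforced by
the volumetric penalty with κ = 10³·μα per element; with uniform 2×2×2
reduced integration the quadratic hexahedra do not lock at this ratio
(verified by the Laplace-law inflation check).

## Solver

Total-Lagrangian quasi-static equilibrium with Newton iteration.
Pressures (IOP and puff) are follower loads: their virtual work is
evaluated on the deformed surface, and the (nonsymmetric) load-stiffness
term enters the tangent.  The linear solver is sparse LU on the free dofs
with a reverse-Cuthill–McKee ordering (low fill at these shell sizes);
within one Newton loop the factorisation is reused while the residual
keeps contracting and refreshed when it stalls — with this steeply
stiffening material a reused iteration costs about a tenth of a
refactorisation, and undamped steps with load-step cutbacks outperform
damped crawling from far away.  Load continuation is adaptive: each
accepted increment seeds the next through a secant predictor and the
increment size is carried across scheduled steps; a failed increment
(no contraction, residual blow-up, element inversion) is bisected down to
1/256 of the step before the solver reports failure, carrying the last
converged state.  Convergence requires the residual below 10⁻⁶ of the
external-force norm, with a secondary displacement-stationarity criterion
(updates below 10⁻⁹ mm) for the near-rigid regime where the assembly
round-off floor exceeds the relative tolerance.  The residual kernel is
numba-compiled (the numpy implementation remains the reference path).
All reductions are ordered, so identical inputs give bit-identical
solutions.  Units are mm–MPa–N; 1 mmHg = 133.322 Pa exactly.

IOP is modelled as a uniform prescribed follower pressure on the inner
surface, not as a volume-coupled cavity: the parametric studies treat IOP
as an independent input, so prescribing it directly matches the study
design.  (During the puff the cavity pressure is held at the prescribed
IOP; a volume-coupled mode was considered and rejected as out of scope
for the study design.)

## Stress-free preload

The design geometry is the pressurised shape, so the unloaded
configuration is recovered by fixed-point iteration: inflate the current
estimate, subtract the mismatch with the design geometry
(X₁ = X₀ − u₀; X_{i+1} = X_i − (x_i − X₀)), three iterations by default
(reproducibility over adaptivity; the count is configurable).  At scleral
strain levels the map contracts strongly — the baseline mismatch falls
from ≈6×10⁻² mm to ≈4×10⁻⁴ mm over three iterations, and the pressurised
image of the final estimate matches the design geometry to ≈5×10⁻⁵ mm,
far below 0.5% of the apex displacement.  Parametric studies re-derive
the stress-free shape for every IOP evaluated (`per_iop`); the inverse
protocol derives it once at the 10-mmHg reference and reuses it at 15–25
mmHg (`fixed_at_reference`), matching the asymmetry of what is anchored
to measurement.

## Air puff

A quasi-static pressure ramp: six equal load steps to a 15.4 kPa peak
(nominally 20 ms — bookkeeping only, inertia is neglected and the
unloading phase is not modelled), applied on the outer equatorial sclera
centred at the uppermost point, with a unit-peak Gaussian spatial kernel.
Kernel distances are measured in the pre-puff configuration (fixed
footprint) while the traction follows the deforming normal.

The footprint width is the one genuinely under-determined load quantity:
the instrument's measured spatial profile is characterised in prior work
on the hardware and is not available here.  The model condition that
anchors it is the published reference deformation — at the baseline
inputs the apex displacement is 1 mm.  The 2.4-mm nozzle bore fails that
condition badly (AD = 0.35 mm, and the AD span over the μ range collapses
to 0.28–0.54 mm instead of the published 0.5–2.5 mm): a free jet spreads
over the ~10 mm standoff, so the wall-pressure footprint must be wider
than the bore.  The package therefore calibrates the width once against
the reference condition — bisection on the monotone AD(width) at the
400-element mesh gives FWHM = 3.3765 mm ≈ 3.38 mm, frozen as the package
default (`airpuff.CALIBRATED_FWHM_MM`; derivation re-runnable via
`airpuff.calibrate_fwhm`).  With it the baseline AD is 1.003 mm and the
μ-range AD span is 0.55–1.71 mm.  The width is a configuration key, and
its effect on the outputs can itself be studied.  Above FWHM ≈ 5 mm at
the full 15.4 kPa peak the shell loses quasi-static stability (local
snap-through), which the solver reports as a step-cutback failure.

## Deformation outputs

The sagittal outer-surface curve is read like an OCT B-scan: the most
anterior point of the scanned region (the local scleral apex, which is
also the puff centre) fixes the lateral origin; heights are sampled at
the fixed lab-frame stations x = −2, 0, +2 mm (Eulerian sampling, as a
segmentation of a B-scan column would), with +x toward the posterior
pole; monotone cubic (PCHIP) interpolation runs along the curve.  From
the pre-puff heights Y and the peak-load heights y:

    AD  = Y₀ − y₀,   CPR = (Y₀ − y₀)/(Y₂ − y₂),   AR = (Y₂ − y₂)/(Y₋₂ − y₋₂).

The +x orientation is the unique choice under which a softer posterior
increases AR above 1 and decreases CPR, consistent with the published
directions; the package asserts this self-test.  The ±2 mm stations are
lab-frame (chord) distances, not arc lengths.  On a fore-aft symmetric
globe (closed shell, AL = EL, uniform wall and stiffness) AR = 1 to
within interpolation error, which is tested.  Ratio denominators below
10⁻⁶ mm raise a reporting error rather than propagating NaNs.

## Parametric studies

*Sensitivity*: each input swept over its range (default 5 points) with
the others at their initial values; summary percent change is measured
from the low to the high end of the range, 100·(y_high − y_low)/y_low
(the published AD span over the μ range is consistent with this
definition; the alternative initial-to-high reading is also reported).
*Random sampling*: all six inputs drawn independently and uniformly over
their ranges (μ_post as a ratio in [0.25, 1] times the drawn μ), default
400 draws, per-IOP stress-free preload, seeded and reproducible
(bit-identical records for identical seeds); per-pair R² is the squared
Pearson correlation with its p-value, identical to the OLS coefficient of
determination for a simple linear fit.  Correlations are taken against
the drawn inputs — for the posterior coefficient that is the ratio
μ_post/μ, which is the sampled variable; the records table carries the
absolute μ_post as well.  Failed draws (extreme-compliant corners can
lose quasi-static stability) are logged with their inputs and excluded
from the correlations.

The IOP baseline is 18 mmHg (the tabulated initial value; a textual
variant of 15 mmHg exists and is noted — the package uses 18).

## Inverse fit

f_apex(μ) runs the forward model at IOP = 10 mmHg (stress-free derived at
10 mmHg) and returns the squared mismatch with the measured AD; a
bounded golden-section/parabolic-interpolation minimiser (scipy's bounded
Brent, the fminbnd contract) searches μ ∈ [0.05, 0.15] MPa with
xatol = 10⁻⁴ MPa.  AD(μ) is strictly decreasing at fixed IOP, so the
problem is unimodal for attainable targets; an optimum within 4·xatol of
a bound raises a boundary-warning flag.  Solver failures inside the line
search return a large finite penalty (10⁶ mm²) with a warning, never an
exception.  Predictions at 15/20/25 mmHg reuse the 10-mmHg stress-free
geometry, and the RMSE over those held-out points summarises prediction
error.

## Synthetic experiments

`synth.generate_synthetic_experiment` emulates the measurement campaign:
3 eyes × 4 scleral sites (S, I, EN, ET) × IOP {10, 15, 20, 25} mmHg, one
true μ* drawn uniformly (default range 0.06–0.14 MPa) per site, additive
independent Gaussian noise with σ = 0.1 mm (the order of experimental
repeat-measurement scatter), seeded and byte-reproducible.  The
generator uses the same common globe geometry and the same
fixed-at-reference protocol as the inverse fit.  What passing
round-trip tests show: the inverse machinery recovers the coefficient
the forward model encodes, and noise propagates to prediction RMSE at
the injected scale.  What they do not show: fidelity of the constitutive
or geometric model to any real eye — the fixtures inherit every model
assumption (isotropy, the Gaussian footprint, common geometry across
sites, IID noise), so they validate the estimation pipeline, not the
physics.

## Problem sizes and numerical tolerances

Study and acceptance runs use deliberately coarse meshes; the choices and
their measured effects (baseline configuration):

| element budget | AD (mm) | used for |
|---|---|---|
| ~72 | 0.55 | inverse round-trip machinery checks |
| ~100 | 0.66 | random-sampling correlation structure |
| ~200 | 0.85 | direction sweeps, percent changes |
| ~400 | 1.003 | headline values; calibration mesh |
| ~800 | ≈ +0.5% vs 400 | convergence check |

Percent-change and ratio outputs converge much earlier than point values
and are the quantities compared across studies.  Newton tolerance 10⁻⁶
(relative), fixed-point prestress 3 iterations, face quadrature 3×3,
volume quadrature 2×2×2 (uniform reduced), κ/μα = 10³, inverse xatol
10⁻⁴ MPa.  Known limitations: no jet CFD (pressure footprint is a
declared Gaussian approximation), no dynamics or unloading, no contact,
isotropic material, linear axial grading only, and a near-incompressible
penalty rather than a mixed formulation.
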