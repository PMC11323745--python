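# sclerapuff

Finite-element simulation of **air-puff deformation imaging (APDI) of the
rabbit sclera**: a parametric globe model with a graded one-term Ogden
sclera, intraocular-pressure (IOP) preload with stress-free geometry
recovery, a quasi-static air-puff load, the deformation outputs AD / CPR /
AR, one-at-a-time and random-sampling parameter studies, and bounded
inverse estimation of the scleral material coefficient from
apex-displacement-vs-IOP measurements.

The package is for biomechanics researchers who want to reason about what
scleral air-puff measurements can and cannot identify: how the deformation
response depends on tissue stiffness, wall thickness, IOP and globe
dimensions, and how well a single stiffness coefficient can be recovered
from AD-vs-IOP curves.

## Model in brief

* **Geometry** — a shell of revolution: exterior ellipse with axial
  diameter AL and equatorial diameter EL; wall thickness THK at the
  equator grading to 0.6 mm at the posterior pole; a spherical-cap cornea
  (0.4 mm thick) at 120° from the optic nerve, apex 1 mm beyond the
  ellipse.  Quarter model with two symmetry planes, meshed into 20-node
  hexahedra.
* **Material** — isotropic, nearly incompressible one-term Ogden solid;
  under uniaxial tension `σ(λ) = μ (λ^α − λ^(−α/2))` with α = 40 fixed and
  μ in MPa the unknown of interest (baseline 0.083 MPa).  μ decreases
  linearly from the equator to the posterior pole (ratio μ_post/μ in
  [0.25, 1]).
* **Loads** — IOP as a follower pressure on the cavity wall, applied on a
  stress-free geometry recovered by fixed-point iteration (3 iterations),
  so the pressurised shape matches the design geometry; then a 6-step
  quasi-static air puff (peak 15.4 kPa, Gaussian footprint) centred on the
  uppermost equatorial point.
* **Outputs** — from the sagittal surface profiles before (Y) and at peak
  load (y), sampled at lab-frame stations x = −2, 0, +2 mm:
  `AD = Y₀ − y₀`, `CPR = AD / (Y₂ − y₂)`, `AR = (Y₂ − y₂)/(Y₋₂ − y₋₂)`.
* **Inverse** — `f_apex(μ) = (AD_sim(μ; 10 mmHg) − AD_meas)²` minimised by
  bounded golden-section/parabolic search over μ ∈ [0.05, 0.15] MPa, then
  AD predicted at 15/20/25 mmHg and scored by RMSE.

See `docs/methods.md` for assumptions, parameter defaults (and why), and
numerical choices — including the one calibrated quantity, the air-puff
footprint width (FWHM 3.38 mm, set once so the baseline model produces
the reference 1-mm apex displacement).

## Worked example

```python
from sclerapuff import run_forward

res = run_forward(resolution=400)   # baseline virtual eye, study mesh
print(f"AD  = {res.outputs.ad:.3f} mm")
print(f"CPR = {res.outputs.cpr:.3f}")
print(f"AR  = {res.outputs.ar:.3f}")
print("stress-free mismatch per iteration [mm]:",
      [f"{h:.2e}" for h in res.stress_free.history])
```

prints

```
AD  = 1.003 mm
CPR = 1.995
AR  = 1.022
stress-free mismatch per iteration [mm]: ['5.91e-02', '2.01e-03', '3.84e-04']
```

AD ≈ 1 mm is the reference deformation of the baseline eye (μ = 0.083
MPa, THK = 0.35 mm, IOP = 18 mmHg).  CPR ≈ 2 says the apex moves twice as
far as the point 2 mm toward the posterior pole; AR ≈ 1 says the
deformation is nearly fore-aft symmetric when the stiffness is uniform
(softening the posterior sclera drives AR above 1).  The stress-free
iteration contracts by ~30× per pass, so the pressurised geometry matches
the design geometry to about 5×10⁻⁵ mm.

The same pipeline is scriptable from the shell:

```bash
sclerapuff solve --config examples/baseline.yaml          # ~2 min
sclerapuff sensitivity --points 3 --resolution 200        # ~6 min
sclerapuff sample --n 400 --seed 1 --resolution 100       # ~20 min
sclerapuff fixtures --eyes 3 --noise 0.1 --seed 1 --resolution 100 --outdir fix
sclerapuff invert fix/synthetic_curves.csv --resolution 100
```

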