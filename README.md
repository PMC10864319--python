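# shakeflask

Post-processing and modelling toolbox for the hydrodynamics of orbitally
shaken (Erlenmeyer-type) flasks: parametric flask geometry, an inviscid
mechanistic model of the rotating liquid distribution, probe-based
contact-line and wall-film extraction from volume-of-fluid (VOF) fields,
volumetric power input from energy dissipation and from a Ne′–Re
correlation, and a synthetic VOF-field generator with analytic ground
truth for validating the whole pipeline.

## What it models

An unbaffled shake flask on an orbital shaker (shaking diameter `d0`,
frequency `n`) carries its liquid as a rotating crescent pressed against
the wall by the centrifugal acceleration `ω² d0/2`, `ω = 2πn`.  The
package covers the desk-scale side of a CFD validation workflow:

- **`geometry`** — the inner flask wall as a solid of revolution: a flat
  bottom, a torus section (radius 14.5 mm by default) and a cone.  Two
  variants: *sharp* (quarter torus, 90°, cone half-angle 16.76° from the
  printed rim diameters) and *smooth* (the torus arc is extended until
  its tangent lines up with a cone anchored at the top rim; the tangency
  is root-found at 107.18° for the default 250 mL dimensions).  Radius,
  volume, wall-normal and wall-distance queries back everything else.
- **`kinematics`** — operating conditions, fluid properties and the
  rotating centrifugal force with a 0.5 s linear start-up ramp.
- **`mechanistic`** — the inviscid model of the liquid distribution: the
  free surface is a paraboloid `h(s) = z0 + ω²/(2g) · s²` about an axis
  offset by `d0/2`; the apex height `z0` is root-found so the volume
  enclosed between paraboloid and wall matches the fill volume, and the
  contact line is the paraboloid/wall intersection per azimuth.
- **`extraction`** — solver-agnostic contact-line extraction: α is
  sampled on a wall-following probe grid (0.5 mm height steps, 1°
  azimuth steps, wall-normal offsets 50–1050 µm), thresholded at 0.5,
  and each air→water crossing is recorded.  Comparing offsets brackets
  the wall-film thickness; the apex azimuth measures the phase lag of
  the liquid behind the centrifugal direction.
- **`dissipation`** — volumetric power input `P/V = ρ·ε` from cell data,
  with `ε = (ν|S| + β* k ω_t)` averaged over the liquid using `V_i α_i`
  weights (`|S|` the squared strain measure, `β* = 0.09`).
- **`correlation`** — `Re = ρ n d²/η`, `Ne′ = 70 Re⁻¹ + 25 Re⁻⁰·⁶ +
  1.5 Re⁻⁰·²`, `P = Ne′ ρ n³ d⁴ V_L^{1/3}` with `d` the maximal inner
  flask diameter (81.6 mm).
- **`synthetic`** — analytic VOF fields (mechanistic bulk, optional
  azimuthal phase shift, optional wall film with tapered top, interface
  smearing), a wall-conforming cylindrical mesh with 100 µm wall layers,
  and analytic flow profiles (quiescent, solid-body, shear layer) whose
  dissipation is known in closed form.
- **`vtkio` / `config` / `cli`** — legacy-ASCII VTK and STL writers and
  readers, strict YAML run configuration, and a `shakeflask` command
  line binding the stages together.

## Worked example

```python
from shakeflask import (FlaskDimensions, FlaskGeometry, OperatingCondition,
                        FluidProperties, solve_fill, power_from_correlation)

geom = FlaskGeometry(FlaskDimensions(), "smooth")
cond = OperatingCondition.from_rpm(250.0, 0.025, 40.0)   # 250 rpm, 40 mL

dist = solve_fill(geom, cond)
print(dist.max_height)           # 41.96 mm — maximal contact-line height
print(dist.max_height_azimuth)   # 180.0° — opposite the orbit centre

pt = power_from_correlation(cond, FluidProperties(viscosity=1e-3))
print(pt.reynolds)               # 27744
print(pt.power_per_volume)       # 686 W/m^3
```

Or on the command line:

```bash
shakeflask geometry -o out/           # geometry.json + flask.stl
shakeflask mechanistic -o out/        # contact_line.csv + summary.json
shakeflask synth -o out/              # fields.vtk + ground_truth.json
shakeflask extract -o out/ --field-file out/fields.vtk
shakeflask power --grid -o out/       # Ne'-Re table; prints max P/V = 7.36 kW/m^3
```

Every run drops a `provenance.json` with the package version, seed and a
SHA-256 hash of the effective configuration.

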