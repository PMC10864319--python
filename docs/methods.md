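# Methods

Models, numerical choices, parameters and limitations of the
`shakeflask` package.  Millimetres are used inside the geometry and
mechanistic modules (where all lengths are of order 10–100 mm); all
other modules are SI, with conversions at module boundaries.

## 1. Flask geometry

The inner wall is a solid of revolution built from three pieces:

1. a flat bottom of radius `R_c = max_diameter/2 − torus_radius`
   (26.3 mm by default),
2. a torus section `r(φ) = R_c + r_t sin φ`, `z(φ) = r_t (1 − cos φ)`
   with `r_t = 14.5 mm`, starting at the bottom rim (`φ = 0`), and
3. a cone up to the top rim (`top_diameter/2` at `top_height`).

Default dimensions (250 mL Erlenmeyer-type flask): torus radius
14.5 mm, maximal diameter 81.6 mm at height 14.5 mm, top diameter
30.7 mm at height 99 mm, bottom diameter 52.6 mm.  The invariant
`bottom_diameter = max_diameter − 2·torus_radius` ties the bottom rim to
the torus construction.

Two junction variants:

- **sharp** — the torus stops at a quarter arc (`φ = 90°`, the maximal
  diameter); the cone half-angle follows from the two printed rim
  circles, `β = arctan((40.8 − 15.35)/(99 − 14.5)) = 16.76°`.  The wall
  slope is discontinuous at the junction.
- **smooth** — the torus arc is extended beyond 90° until its tangent
  is collinear with the chord from the (moving) torus end point to the
  *fixed* top rim.  The tangency residual `cot φ − (r_top − r(φ)) /
  (z_top − z(φ))` is root-found with Brent's method on `φ ∈ (90°,
  180°)`; for the default dimensions `φ* = 107.18°` and the recomputed
  cone half-angle is 17.18°.  The profile is continuously
  differentiable at the junction by construction.

`inner_volume_below_height` integrates `π r(z)²` with adaptive
quadrature (`scipy.integrate.quad`, absolute tolerance 0.1 mm³);
`height_for_volume` inverts it by bracketing and Brent's method.
`wall_distance` is exact for points near the wall: the distance to the
torus arc (with end-point clamping) is combined with the distance to
the cone segment.

## 2. Shaking kinematics

`ω = 2πn`.  In the flask-fixed frame the centrifugal acceleration
rotates at `ω` with magnitude `ω² d0/2`.  The start-up uses a linear
frequency ramp over the first 0.5 s; the phase is the exact integral of
`ω(t)` over the ramp so force histories are continuous.  Azimuth
convention: the bulk liquid sits at 180° (the centrifugal direction
when the force points along +x at `t` past the ramp); all contact-line
azimuths use this convention.

## 3. Inviscid mechanistic model

In the rotating frame, a liquid with negligible viscosity forms the
equipotential surface of gravity plus the centrifugal field about the
axis through `(d0/2, 0)`:

    h(s) = z0 + c s²,   c = ω² / (2 g),   g = 9.81 m/s²

with `s` the horizontal distance from the offset axis (`c` converted to
1/mm internally).  The liquid area at height `z` is the flask disk minus
the circle–circle lens overlap with the "dry" disk `s < s_dry(z)`
(closed-form lens area, vectorised), and the enclosed volume is its
quadrature over `z`.  `solve_fill` root-finds `z0` (Brent) so the
enclosed volume matches the fill volume to 0.1 % (default tolerance
1e-3 relative); it raises when the fill exceeds the flask volume or the
matched surface would spill over the top rim.

The contact line per azimuth is found from a dense scan (0.05 mm) of
`h(s(z, θ)) − z` along the wall followed by Brent refinement of each
sign change; multiple crossings per azimuth (dry bottom patch at high
frequency and small fill) are returned in descending order with
alternating air→water / water→air directions.

Reference result: 40 mL, 250 rpm, `d0 = 2.5 cm`, smooth variant →
maximum contact-line height 41.96 mm at azimuth 180°, symmetric about
the centrifugal direction.

## 4. Contact-line extraction

`extract_contact_lines` samples any `VolumeFractionField` on a
wall-following probe grid: heights every 0.5 mm (199 rows for the
99 mm flask), azimuths every 1° (360 columns, i.e. ≈ 72 000 probe
positions per offset), at wall-normal offsets {50, 250, 450, 650, 850,
1050} µm along the inward normal.  A sample with `α ≥ 0.5` counts as
water (ties are water); crossings are recorded walking downward from
the flask top at the midpoint of the bracketing samples, so heights are
exact to half a z-step on sharp fields.  Note the probe ray follows the
wall normal, so on the cone a reported height at offset `δ` is shifted
by `δ sin β` relative to the geometric interface height.

Derived diagnostics:

- **Film bracketing** (`estimate_film_thickness`): over a 90° azimuth
  window opposite the bulk (315°–45°), offsets still inside a wall film
  report the film-top height while offsets beyond it drop to the bulk
  contact line (or to nothing).  The first offset that drops gives the
  bracket `(previous, first)` in µm; no film → `(0, 50)`; film thicker
  than the ladder → `(1050, ∞)`.  A 500 µm synthetic film brackets as
  (450, 650) µm.
- **Apex shift** (`apex_shift`): the azimuth of the maximal contact
  height (circular mean over ties within a quarter z-step) minus the
  180° reference, wrapped to (−180°, 180°].  Flat contact lines are
  rejected as undefined.

`NearestPointField` mirrors probe sampling of solver output: nearest
cell-centre lookup (`scipy.spatial.cKDTree`) with a 5 mm support
radius; farther queries are air and logged.

## 5. Power input from dissipation

Per cell, the specific dissipation is `ε_i = ν |S|_i + β* k_i ω_i` with
`β* = 0.09` and the squared strain measure

    |S| = 2(u_x² + v_y² + w_z²) + (u_y + v_x)² + (v_z + w_y)² + (u_z + w_x)²

(units 1/s²; zero for rigid rotation, `γ̇²` for simple shear).  The
liquid average uses `V_i α_i` weights; `P = ε ρ Σ V_i α_i` and
`P/V = P / V_ref` where `V_ref` defaults to the α-weighted liquid
volume and can be overridden with a nominal fill volume — recommended
when the field carries a wall film, since the film adds ~10 % liquid
volume but a negligible share (≪ 1 %) of the dissipation integral.
Gradients are supplied with the field (analytic for synthetic fields,
solver-exported otherwise); the package does not differentiate velocity
fields numerically.

## 6. Ne′–Re correlation

    Re  = ρ n d² / η                 (d = 0.0816 m, maximal inner diameter)
    Ne′ = 70 Re⁻¹ + 25 Re⁻⁰·⁶ + 1.5 Re⁻⁰·²
    P   = Ne′ ρ n³ d⁴ V_L^{1/3}

The shaking diameter does not enter.  Representative values: Re ≈
27 700 (water-like 1 mPa·s at 250 rpm), ≈ 1 660 (16.7 mPa·s, 250 rpm),
≈ 56 100 (0.89 mPa·s, 450 rpm).  Over the grid 180–380 rpm × {25,
40} mL × {1, 16} mPa·s the maximum P/V is 7.36 kW/m³ (rounds to
7 kW/m³), monotone increasing in `n` and `η` and decreasing in `V_L`.

## 7. Synthetic field generator

Purpose: stand in for interface-capturing solver output so the
extraction and dissipation stages can be validated against analytic
ground truth.  It is **not** a flow solver; its artefacts are
parametric, not dynamic.

The α field is built from a signed indicator `f = max(f_bulk, f_film)`:

- `f_bulk` — vertical signed distance below the mechanistic paraboloid,
  optionally rotated by a `phase_shift` (emulating the viscous lag of
  15–30° seen at elevated viscosity);
- `f_film` — `min(t(z) − d_wall, z_filmtop − z)` for a wall film of
  thickness `t` (realistic range 50–800 µm) up to a configurable top
  height (default: the bulk maximum), with a 10 % linear taper over the
  top tenth of the film;
- `α = clip(0.5 + f/w, 0, 1)` smears the interface over
  `interface_smear_cells` z-cells (default one), mimicking compressed
  VOF interfaces.  Films thinner than half a wall layer are flagged
  sub-resolution and logged.

The mesh is a wall-conforming cylindrical-shell grid: per height, the
outer `n_wall_layers` (default 12) cells are fixed 100 µm wall layers
and the core is split uniformly; defaults give ≥ 20 cells across the
diameter (enforced).  Cell volumes use 3-point Gauss quadrature per
z-layer so they sum to the flask volume; cell α values use 27-point
area-weighted subsampling.

Flow profiles with closed-form dissipation: `quiescent` (ε = 0),
`solid_body` (rigid rotation at `ω`; ε = β* k ω_t exactly, with uniform
k = 1e-3 m²/s², ω_t = 10 1/s), `shear_layer` (uniform `du_x/dz =
100 1/s` in the bulk; ε = ν γ̇² exactly; gradients inside the film
attenuated ×1e-3 to model quasi-static drainage).

## 8. File formats and configuration

VTK output/input is legacy ASCII unstructured-grid (hexahedra from the
cylindrical mesh), written and parsed in-package; points are mm, the
`volume` array is m³ and all field arrays SI.  When reading files
without a `volume` array, cell volumes are recomputed from a
six-tetrahedron decomposition of each hexahedron (≈ 1 % low for curved
cells — prefer the stored volumes).  STL export is ASCII, mm.  YAML run
configs are strictly validated: unknown keys fail with a message naming
them.  Each CLI run writes `provenance.json` (package version, seed,
SHA-256 of the effective configuration).

## 9. Limitations

- No flow solver: liquid distributions are inviscid equilibria; viscous
  lag, waves, breakup and turbulence are only *emulated* by the
  synthetic generator's parameters.
- The mechanistic model ignores surface tension and contact angle
  (stored on `FluidProperties` for completeness); it is a bulk-shape
  model, accurate to a few millimetres for water-like fluids.
- Dissipation requires gradients/k/ω supplied per cell; no numerical
  differentiation of velocity fields is performed.
- The Ne′–Re correlation applies to unbaffled flasks in the in-phase
  operating regime; out-of-phase conditions are out of scope.
- The extraction reports heights on the probe grid (half z-step
  quantisation) and along tilted wall-normal rays (offset-dependent
  shift on the cone, see §4).
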