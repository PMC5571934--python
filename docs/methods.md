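# Methods

## Geometric model

Both leaflets are modelled as portions of elliptic cylinders
`θ(y1, y2) = (a cos y1, b sin y1, h y2)`. The coordinate convention is:
x along the inter-commissural (IC) axis, y along the septolateral axis
(anterior side positive, posterior negative), z the height axis; units
are centimetres and radians throughout. The anterior patch uses
`y1 ∈ [0, π]` (so y ≥ 0) with semi-axes `(IC/2, SL_ant)`; the
posterior patches use `y1 ∈ [π, 2π]` (y ≤ 0) with `(IC/2, SL_post)`.
The two shells interface because the anterior ellipse's major axis
equals the posterior ellipse's minor axis — both are IC/2 — so the
patches share exactly the two commissure points `(±IC/2, 0, 0)`.

### Posterior partition and junction continuity

The posterior interval `[π, 2π]` is divided among P1, P2 and P3 in
proportion to their nominal widths. Each scallop free edge is a sine
ramp; the frequencies are not free parameters but are derived from a
single *junction phase* `φ`:

- `c1 = φ / (θ1 − π)` — P1's edge reaches phase φ at the P1/P2
  junction `θ1`;
- `c2 = π / (θ2 − θ1)` — P2's edge completes a half period across its
  interval;
- `c3 = φ / (2π − θ2)` — P3, mirrored.

With `φ = 8π/9` and the default widths 1.6/2.3/1.5 this reproduces the
canonical frequencies 3, 54/23 and 16/5 exactly (a rational-arithmetic
identity checked in the tests). Treating φ as the primitive parameter,
rather than the three frequencies separately, keeps the model
continuous for *any* widths and heights: the P2 band is lifted by
`δ = h_p1 sin(π − φ) / h_p2`, which equates the free-edge height on
both sides of θ1, and the edge is continuous at θ2 exactly when
`h_p1 = h_p3` (true at the defaults). `check_continuity` reports the
residual gap; `δ ≥ 1` (a middle scallop too short to reach the
junction height) is rejected as infeasible rather than clipped, since
clipping would silently break the continuity the offset exists to
provide.

Scallop intervals are half-open `[lo, hi)` with P3 closed at 2π; a
point query at a junction angle resolves to the right-hand scallop,
and continuity makes the choice physically irrelevant. Point
evaluation on the posterior side accepts `y2` from the annulus (0) up
to the free edge — the strip below the P2 band offset is the leaflet's
attachment region — while the meshed P2 band spans `[δ, edge]`, which
is what the lifted free-edge construction prescribes.

### Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| `ic` | inter-commissural diameter | 2.8 | cm |
| `sl_ant`, `sl_post` | septolateral semi-depths | 1.04, 2.11 | cm |
| `h_ant, h_p1, h_p2, h_p3` | leaflet heights | 2.4, 1.1, 1.4, 1.1 | cm |
| `w_ant` | anterior width (metadata) | 3.6 | cm |
| `w_p1, w_p2, w_p3` | scallop widths (partition weights) | 1.6, 2.3, 1.5 | cm |
| `phi` | junction phase | 8π/9 | rad |

The defaults are the nominal healthy-adult dimensions from published
cohort morphometry. Two deliberate choices:

- **P3 height defaults to 1.1 cm**, the coefficient of the P3 surface
  equation, although 1.0 cm also circulates as the P3 tabulated
  central height; 1.0 is accepted via configuration. The surface
  equations are taken as normative; the package records both rather
  than silently reconciling them, and the synthetic-cohort sampler
  uses the tabulated range (0.6–1.7 cm) regardless.
- **`w_ant` is metadata only.** The anterior patch always spans its
  full semi-ellipse, whose arc length (≈ 3.87 cm for semi-axes
  1.4/1.04) is not the nominal 3.6 cm width; the measurement report
  shows nominal and realised arc widths side by side instead of
  asserting equality. The same applies to the scallops: proportional
  *angular* partitioning does not reproduce the widths as arc lengths.

## Meshing

Each patch's non-rectangular domain is sampled on a band-normalised
structured grid: `n_u` angles times `n_v` levels with
`y2 = lower + v (upper − lower)`. The angle grids always include the
interval endpoints, the interior maximum of each free edge, and 3π/2
on the posterior side, so axis extents and maximum heights of the
meshed surface are attained exactly at any resolution rather than
approached from below. Columns where the band collapses (commissures,
the P2 junction columns) degenerate to a single vertex; after welding
(tolerance 1e-9 cm, far below any feature size), triangles with area
below 1e-12 cm² are culled. Each scallop is meshed separately and the
junction columns welded, because the posterior bound functions are
only piecewise smooth. Winding is oriented so normals point away from
the cylinder axis. The default 200×50 per-patch resolution keeps the
total area within 0.1% of the exact value and builds in well under a
second; tests use coarser grids where only topology or exact extents
matter.

## Measurement

Leaflet maximum heights are computed in closed form (`h` when the sine
reaches 1 inside the interval, else `h sin` at the boundary). Arc
lengths use adaptive quadrature of the ellipse arc element
`√(a² sin²t + b² cos²t)` at relative tolerance 1e-9 — far below the
two-decimal precision of any published dimension. Surface areas exploit
developability: a cylinder patch's area is the 1-D integral of band
height times the arc element, which serves as the oracle the summed
triangle areas must converge to. Range validation checks heights and
nominal widths against the published healthy-cohort ranges (anterior
2.5–4.8 / 2.0–3.0, P1 0.9–4.0 / 0.9–2.0, P2 1.3–3.8 / 0.9–2.0, P3
0.9–3.1 / 0.6–1.7 cm, width/height); the ranges are overridable for
other populations.

## Synthetic cohorts

`cohort.sample_parameters` draws leaflet heights and widths within the
published ranges, by default uniformly — the source table gives
central values and ranges but no distribution, so uniform is the
least-assumption choice — with a triangular option peaked at the
central value. Dimensions are drawn independently (no covariance is
published) and the annulus stays at its nominal values unless an
explicit jitter fraction is given, because no population range exists
for it. Draws violating junction feasibility (`δ ≥ 1`) are rejected
and resampled with a bounded retry budget. Consequences for what the
tests show: a passing cohort run demonstrates determinism, range
compliance and geometric feasibility, but nothing about real
covariance between valve dimensions, annulus variability, or
non-uniform population structure.

## Numerical choices

- Welding key: coordinates rounded to the 1e-9 cm grid; idempotent by
  construction, and coincident junction vertices agree to ~1e-16 cm so
  the tolerance has orders of magnitude of slack.
- Degenerate-face threshold 1e-12 cm²; at desk scale the smallest real
  triangles are ~1e-5 cm².
- Extent and height assertions use absolute tolerance 1e-12 cm: the
  forced grid points make these quantities exact up to floating
  rounding of the trigonometric evaluations.
- Quadrature: `scipy.integrate.quad`, relative tolerance 1e-9,
  subdivision limit 200.
- Angles are radians internally; configuration accepts degrees only
  through an explicit `{value, unit: deg}` tag.

## Known limitations

- The leaflets are surfaces, not solids: no thickness, and no chordae
  or papillary geometry.
- Static geometry only; no mechanics or dynamics.
- The model "width" of a region is a partition weight, not an arc
  length (see above).
- Free-edge continuity at the P2/P3 junction requires `h_p1 = h_p3`;
  for unequal outer scallop heights the model reports, rather than
  removes, the resulting step.
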