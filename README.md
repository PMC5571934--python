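# mitralgeom

A parametric geometric model of the human mitral valve, with surface
meshing, morphometric measurement and synthetic-cohort sampling.

The mitral valve — the inflow valve of the left ventricle — has an
anterior leaflet (one wide cusp) and a posterior leaflet of three
narrow scallops, P1, P2 and P3, attached to a saddle-shaped annulus.
`mitralgeom` realises a closed-form model of this anatomy for people
who need an explicit, parameterisable valve surface: meshes for
finite-element or fluid–structure simulation, printable prosthesis
prototypes, or simply reproducible morphometry against published
population ranges.

## The model

The annulus is two semi-ellipses sharing the inter-commissural (IC)
axis: the anterior semi-ellipse has semi-axes (IC/2, SL_ant), the
posterior (IC/2, SL_post), where SL_ant + SL_post is the septolateral
diameter. Each leaflet is a portion of the corresponding semi-elliptic
*cylindrical* shell

```
θ(y1, y2) = (a cos y1, b sin y1, h y2)
```

with `y1` the annulus angle, `y2` the normalised height and `h` the
leaflet height. Free edges are sine curves in the parameter plane:

- anterior: `y1 ∈ [0, π]`, `y2 ∈ [0, sin y1]`;
- posterior: `y1 ∈ [π, 2π]` split among P1, P2, P3 in proportion to
  their widths `w_p1 : w_p2 : w_p3`, each scallop carrying a sine edge
  `sin c_i (…)` whose frequency `c_i` is fixed by a junction phase
  `φ` (default `8π/9`) so that the free edge meets its neighbour at
  the same height. The middle scallop's band is lifted by the offset
  `δ = h_p1 sin(π − φ) / h_p2`, which makes the free edge
  height-continuous across both junctions.

Nominal (healthy-adult) defaults: IC = 2.8 cm, SL_ant = 1.04 cm,
SL_post = 2.11 cm; leaflet heights 2.4 / 1.1 / 1.4 / 1.1 cm and widths
3.6 / 1.6 / 2.3 / 1.5 cm for anterior / P1 / P2 / P3. With these the
junction angles are exactly 35π/27 and 93π/54 and the sine frequencies
3, 54/23 and 16/5.

## Worked example

```python
from mitralgeom import (
    ValveParameters, MeshResolution, mesh_valve,
    axis_extent, leaflet_max_height, check_continuity, surface_area,
)

params = ValveParameters()          # nominal healthy-adult valve
mesh = mesh_valve(params, MeshResolution(200, 50))

print(f"IC (x extent):            {axis_extent(mesh, 'x'):.2f} cm")
print(f"septolateral (y extent):  {axis_extent(mesh, 'y'):.2f} cm")
print("leaflet max heights:     ",
      {l: round(leaflet_max_height(params, l), 2)
       for l in ("anterior", "P1", "P2", "P3")})
print(f"free-edge junction gap:   {check_continuity(params):.1e} cm")
print(f"total leaflet area:       {surface_area(params):.3f} cm^2")
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces")
```

prints

```
IC (x extent):            2.80 cm
septolateral (y extent):  3.15 cm
leaflet max heights:      {'anterior': 2.4, 'P1': 1.1, 'P2': 1.4, 'P3': 1.1}
free-edge junction gap:   1.7e-16 cm
total leaflet area:       10.151 cm^2
mesh: 39952 vertices, 78204 faces
```

The extents recover the annulus dimensions (the IC diameter and the
septolateral diameter), the height row matches the nominal leaflet
heights, and the junction gap is zero to machine precision — the
continuity the offset `δ` is constructed to guarantee. The area is the
developable-surface quadrature value; the mesh's summed triangle area
converges to it under refinement.

## Command line

```sh
mitralgeom generate -o valve.stl          # default valve mesh (STL, OBJ, PLY)
mitralgeom measure --format csv           # morphometry report
mitralgeom validate                       # range checks; exit 1 on failure
mitralgeom cohort -n 50 --seed 42         # synthetic parameter cohort (CSV)
```

All dimensions are centimetres; pass `--mm` to `generate` for
millimetre output (3D-printing convention). Configuration is a small
YAML file with strict schema checking; an empty file means the nominal
valve (see `docs/methods.md`).

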