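# Methods

This note records the models, conventions and numerical choices behind
`morpho3d`, in the spirit of a methods section: what each procedure
assumes, which knobs matter, and what the synthetic tests do and do not
demonstrate about real microscopy data.

## Coordinate and unit conventions

Label volumes are indexed `(z, y, x)` with per-axis spacing in the same
order; voxel index `i` maps to the physical position `origin + i·spacing`
of the voxel *center*. Meshes live in a right-handed `(x, y, z)` physical
frame. The package never converts units: every output inherits the length
unit of the input (µm by convention throughout the docs). All randomness
funnels through `numpy.random.default_rng(seed)`; every stochastic
operation takes an explicit seed and is reproducible.

## Mesh input and normalization

The OBJ reader consumes only `v` and `f` records (polygon faces are
fan-triangulated from their first vertex; `vt`/`vn` components and
materials are ignored; negative indices are resolved per the OBJ
standard). On load, faces with repeated indices or zero area are dropped
with a logged count — marching-cubes output and hand-edited meshes both
contain such slivers, and dropping them keeps area and volume
well-defined. Winding is then made consistent per connected component by
breadth-first face traversal, and each *closed* component is flipped, if
necessary, so its signed volume is non-negative. This is the
interpretation adopted for "orientation assignment" on import: winding
consistency, not axis remapping (axis transforms are left to the caller).

## Area, volume, watertightness

Surface area is the exact sum of triangle areas. Enclosed volume is the
divergence-theorem sum `Σ a·(b×c)/6`, exact for closed consistently wound
surfaces and translation-invariant. A mesh counts as watertight when every
undirected edge is incident to exactly two faces *and* every directed edge
appears exactly once (consistent winding). Volume of an open mesh is
refused by default — the volume of a non-closed segment is biologically
undefined — with the boundary-edge count attached to the error; an
`allow_open=True` escape hatch returns the raw signed sum for power users.
Batch measurement reports open meshes as rows with a missing volume and a
warning code rather than aborting.

## Label volumes to meshes

Each label's binary mask is padded by one background voxel on every face
(so objects touching the stack border still produce closed surfaces) and
passed to marching cubes at iso-level 0.5 with the physical spacing;
vertices are then shifted back by one voxel and mapped to the `(x, y, z)`
frame. The raw marching-cubes surface is exported unsmoothed and
undecimated, keeping measured areas and volumes deterministic functions of
the mask. At iso-level ½ the recovered volume converges to
`voxel_count × voxel_volume` as the object diameter in voxels grows; the
ball fixtures show the relative error falling monotonically from radius 5
to 20 voxels (~0.5 % at r = 20).

## Cross-sections

A center line is an ordered polyline; stations are arc-length coordinates.
`build_centerline` can also fit one automatically as the dominant
principal direction of the vertex cloud through its centroid, clipped to
the extent of the vertex projections. If the top two covariance
eigenvalues differ by less than 10 % the axis is geometrically ambiguous
(e.g. a sphere); the line is still returned but flagged `low_anisotropy`.
A perfectly collinear cloud is rejected.

Planes are placed at `(i + ½)·Δ` so both ends are inset by half a step —
the tangent is undefined exactly at polyline endpoints — with the normal
equal to the containing segment's direction, or the normalized mean of the
two adjacent directions at an interior polyline vertex. A requested step
longer than the line yields one mid-line plane with a warning.

Plane–mesh intersection computes one segment per crossing triangle and
chains segments into loops *by shared mesh-edge identity*: the two
endpoints of a triangle's crossing segment lie on specific mesh edges, and
on a watertight mesh each crossed edge is shared by exactly two crossing
triangles, so chaining is exact and tolerance-free. Vertices lying within
`1e-9 × bbox` of the plane are first nudged to the positive side, removing
the triangle-in-plane degeneracy. Open chains (possible only when the
plane cuts a mesh boundary) are reported and excluded from properties.
Loops are classified outer/hole by containment parity and normalized to
counter-clockwise outers / clockwise holes.

Section properties follow the conventions of standard 2D region-properties
tools so users can compare against image-based measurements:

- area = outer − holes (signed shoelace);
- perimeter includes hole boundaries (a lumen adds boundary), and
  convexity-by-perimeter is therefore hull-over-total, keeping it ≤ 1;
- the convex hull is taken over all ring vertices;
- equivalent diameter is the Heywood diameter `√(4A/π)`;
- axis lengths are `4√λ` for the eigenvalues λ of the area-normalized
  second central moment matrix of the (hole-subtracted) region, i.e. the
  axes of the moments-equivalent ellipse, computed from closed-form
  Green's-theorem polygon moments rather than a minimum bounding box. The
  unit square then has both axes `2/√3 ≈ 1.155`, and an n-gon approximating
  a circle of radius r has both axes → 2r. These choices were validated
  against an independent oracle that rasterizes the region at 2048² and
  computes discrete moments.

Cavalieri consistency — the trapezoid integral of section areas along a
straight center line reproducing the divergence-theorem volume to ≲ 2 %
at 200 stations — ties the sectioning and volume codes together through
two independent routes.

## Skeletonization

The skeletonizer is a TEASAR-family algorithm operating per 26-connected
foreground component:

1. **DBF.** Euclidean distance to the nearest background voxel
   (anisotropy-aware; the array border counts as background), which also
   serves as the local radius estimate attached to each node.
2. **Root.** Two-pass farthest-point search (Dijkstra with physical edge
   lengths on the 26-neighborhood graph) from the lowest-linear-index
   seed, followed by endpoint recentering (below).
3. **Paths.** Edge weights are multiplied by the mean endpoint penalty
   `1 + 5000·(1 − DBF/DBF_max)^4`; the exponent 4 sharpens ridge-following
   along the DBF crest. Repeatedly: pick the not-yet-invalidated voxel
   farthest (Euclidean-geodesically) from the root, recenter it, and trace
   the penalized shortest path from it to the *current skeleton* — a
   multi-source Dijkstra from all voxels already on the skeleton. Ending
   paths at the nearest skeleton voxel (rather than reusing one fixed
   root-tree) guarantees each new branch attaches at the true junction;
   with a single tree, two parallel ridge rails can run side by side and
   merge far from the anatomical branch point.
4. **Invalidation.** Every voxel within `scale·DBF(node) + const` of a
   path node is invalidated; iteration stops when no valid voxels remain.
   Defaults: `scale = 2`, `const =` one mean voxel length. Larger `scale`
   never increases the node count.
5. **Endpoint recentering.** Farthest-point endpoints land on surface
   corners (e.g. a tube's cap rim, ~r off-axis). Each endpoint is moved by
   strict ascent of the DBF over the 26-neighborhood, with total travel
   capped at `scale·DBF + const` of the voxel reached — so the original
   endpoint always remains inside the final node's invalidation ball and
   termination is guaranteed. On the straight-tube fixture this brings
   every node onto the axis at the cost of ~one radius of length at each
   end (52 µm recovered for a 60 µm tube).
6. **Spur pruning.** Leaf branches shorter than
   `max(2·DBF(junction), const)` are deleted iteratively; these are
   voxelization whiskers. Components with no junction (pure paths) are
   never pruned.

All tie-breaks resolve to the lowest linear voxel index, so identical
inputs and parameters give identical skeletons. The output is a forest
(one root per component) serialized as SWC with 1-based ids, parents
preceding children, and the DBF as the radius column. Bit-parity with any
particular external skeletonizer is a non-goal; the contract is the
topology/centering/determinism behavior above.

`voxelize` bridges meshes to the voxel skeletonizer: a voxel is foreground
iff its center is inside the watertight mesh, decided by crossing parity
along +x rays (rays carry a tiny deterministic offset so edge/vertex hits
have measure zero).

## Distances

Surface distance is the shortest path on the vertex–edge graph with
Euclidean weights — deliberately *not* an exact polyhedral geodesic: it is
exactly reproducible, oracle-checkable (the suite compares 150 random
pairs against exhaustive Bellman–Ford relaxation at 1e-12), and an upper
bound on the true geodesic (≈ +5 % on a subdivision-4 icosphere for
antipodal points, shrinking with refinement). Dijkstra runs with
deterministic lexicographic predecessor tie-breaking. Points are attached
by nearest-vertex snapping (ties to the lowest index) with the snap
distance reported, replacing interactive picking.

## Angular distribution

`fixed` defaults to the area-weighted surface centroid — deterministic and
landmark-free; pass an explicit anchor when a biological landmark exists.
Sampling is uniform by surface area (triangle choice ∝ area, uniform
barycentric via the square-root trick), making the statistic independent
of tessellation density; a `vertex` mode exists for parity with tools that
sample mesh vertices. The standard deviation is the population form. The
reported mean lies in [0, π]; for a sphere of radius a at distance d every
angle is bounded by the tangent-cone half-angle `arcsin(a/d)`, one of the
test oracles. Interpretation (larger mean = broader spread) is left to the
user; the statistic itself is purely geometric. Defaults:
`n_samples = 10 000`, `seed = 0`.

## Synthetic fixtures and what the tests show

`morpho3d.synthetic` generates every test input: icospheres, boxes,
cylinders and tori as meshes (with frozen refinement-dependent error
bounds relative to their closed forms), and balls, capped tubes, Y-shaped
capsule unions and multi-label ball grids as label volumes (with recorded
voxel counts, axes, tips and junctions). Fixture sizes used by the suite
and the acceptance script — sphere r = 10 (subdiv 2–4), ball r = 20 vox,
tube r = 4 × 60 vox, Y arms 30 vox — keep the full run under a minute
while leaving each criterion's tolerance comfortably resolvable.

These shapes pin down correctness of the geometry engines, but they are
smooth, noise-free and simply shaped. Passing tests therefore demonstrate
algorithmic correctness, not robustness to segmentation noise, anisotropic
staircase artifacts at extreme spacing ratios, touching objects, or
topological defects in real segmentations — on such data the openness
checks, skip-and-warn bulk import and open-chain reporting are the
designed failure paths.

## Known limitations

- Surface distance is an edge-graph upper bound, not an exact geodesic.
- Cross-section axis lengths follow the moment convention; tools using
  minimum bounding rectangles will differ on elongated concave sections.
- The skeletonizer targets topology and centering, not bit-parity with
  other TEASAR implementations; very thin (1-voxel) structures skeletonize
  but their radii are quantized to the voxel size.
- `voxelize` is O(rays × triangles) and intended for meshes up to ~10⁵
  faces at moderate grid sizes.
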