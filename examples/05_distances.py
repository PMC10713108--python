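"""Straight vs on-surface distance between two points on a mesh.

For two near-antipodal points on a sphere of radius 10 µm the straight
distance is the chord (~20 µm) while the on-surface path must walk half a
great circle (~31.4 µm).
"""

import numpy as np

from morpho3d import snap_to_surface, surface_distance
from morpho3d.synthetic import ShapeSpec, make_mesh

sphere, _ = make_mesh(ShapeSpec("icosphere", {"radius": 10.0, "subdivisions": 4}))

a = snap_to_surface(sphere, (0, 0, 10.0))
b = snap_to_surface(sphere, (0, 0, -10.0))
res = surface_distance(sphere, a, b)

print(f"snap distances: {a.snap_distance:.3g}, {b.snap_distance:.3g} µm")
print(f"straight distance: {res.straight:.3f} µm (chord)")
print(f"surface distance:  {res.surface:.3f} µm "
      f"(half great circle = {np.pi * 10:.3f} µm)")
print(f"path: {len(res.path)} vertices along mesh edges")
print("The edge-graph geodesic slightly overestimates the smooth geodesic")
print("because paths are restricted to mesh edges.")
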