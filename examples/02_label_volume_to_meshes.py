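"""From a segmented label volume to surface meshes.

Generates a voxelized ball of radius 20 µm (standing in for one segmented
organelle in a TIFF stack), extracts its surface with marching cubes, and
checks volume agreement. With real data, replace `make_volume` by
`read_label_stack("stack.tif", spacing=(z, y, x))`.
"""

import numpy as np

from morpho3d import enclosed_volume, labels_to_meshes, watertight_info
from morpho3d.synthetic import ShapeSpec, make_volume

vol, rec = make_volume(ShapeSpec("ball_volume", {"radius": 20.0}))
print(f"label volume: shape {vol.shape}, {rec.voxel_count} foreground voxels")

mesh = labels_to_meshes(vol)[1]
v = enclosed_volume(mesh)
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces, "
      f"watertight={watertight_info(mesh).is_watertight}")
print(f"mesh volume {v:.0f} µm³ vs analytic {rec.volume:.0f} µm³ "
      f"({100 * abs(v / rec.volume - 1):.2f}% off)")
print("Marching cubes at iso-level 0.5 recovers the object volume to a few")
print("percent at this resolution; the error shrinks as the object grows.")
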