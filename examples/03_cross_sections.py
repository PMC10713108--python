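"""Cross-section a tubular object along its center line.

Slices a cylinder (radius 3 µm, height 20 µm) perpendicular to its
principal axis and prints the nine geometric properties per section.
"""

from morpho3d import build_centerline, slice_and_measure
from morpho3d.synthetic import ShapeSpec, make_mesh

cyl, rec = make_mesh(ShapeSpec("cylinder", {"radius": 3.0, "height": 20.0}))

# center line inferred from the vertex cloud's dominant principal direction
cl = build_centerline(cyl, method="principal-axis", n_points=2)
table = slice_and_measure(cyl, cl, n_sections=5)
print(table.round(4).to_string(index=False))
print()
print("Every section of this cylinder is a disc of radius 3: area ~28.3 µm²,")
print("equivalent diameter ~6 µm, convexities ~1 (convex), and major ~ minor")
print("axis (no elongation). A real dendrite would show these varying along")
print("the arc-length `station` column.")
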