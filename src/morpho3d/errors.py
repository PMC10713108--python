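"""Exception types shared across the toolbox."""


class Morpho3dError(Exception):
    """Base class for all morpho3d errors."""


class FormatError(Morpho3dError):
    """A file does not conform to its declared format (OBJ, TIFF, SWC...)."""


class OpenMeshError(Morpho3dError):
    """An operation that requires a watertight mesh received an open one.

    Carries ``boundary_edge_count``: the number of undirected edges incident
    to fewer or more than two faces.
    """

    def __init__(self, message: str, boundary_edge_count: int = 0):
        super().__init__(message)
        self.boundary_edge_count = boundary_edge_count


class MissingLabelError(Morpho3dError):
    """Requested labels are absent from a label volume. Carries ``labels``."""

    def __init__(self, labels):
        self.labels = sorted(labels)
        super().__init__(f"labels not present in volume: {self.labels}")


class DegeneracyError(Morpho3dError):
    """Geometric input too degenerate for the requested operation."""


class DegenerateSectionError(Morpho3dError):
    """A cross-section has no closed outer loop or non-positive area."""


class MissesObjectError(Morpho3dError):
    """Every slicing plane along the center line missed the mesh."""


class UnreachableError(Morpho3dError):
    """Two surface points lie in different connected components of a mesh."""

    def __init__(self, message: str, component_a: int = -1, component_b: int = -1):
        super().__init__(message)
        self.component_a = component_a
        self.component_b = component_b
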