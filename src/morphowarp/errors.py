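"""Exception hierarchy for morphowarp."""


class MorphowarpError(Exception):
    """Base class for all package errors."""


class MeshFormatError(MorphowarpError):
    """Raised when an OBJ file cannot be parsed; message names the line."""


class EmptyMeshError(MorphowarpError):
    """Raised when a mesh ends up with zero (valid) faces."""


class GeometryError(MorphowarpError):
    """Degenerate local geometry (zero normal, coincident curve points...)."""


class DegenerateConfigurationError(MorphowarpError):
    """Landmark configuration unusable for TPS (coplanar, duplicates...)."""


class CapacityError(MorphowarpError):
    """Requested more semi-landmarks than the surface region can host."""

    def __init__(self, message: str, max_feasible: int):
        super().__init__(message)
        self.max_feasible = max_feasible


class AmplitudeError(MorphowarpError):
    """Synthetic deformation folded the mesh; reduce the amplitude."""


class DimensionalityError(MorphowarpError):
    """Singular covariance in a multivariate test; reduce dimensions first."""
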