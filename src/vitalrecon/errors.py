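"""Exception hierarchy.

All package-specific errors derive from :class:`VitalReconError` so that
callers (and the CLI) can separate data problems from numerical failures.
"""


class VitalReconError(Exception):
    """Base class for all vitalrecon errors."""


class InvalidInputError(VitalReconError, ValueError):
    """An argument (size, time, weight, ...) is outside its valid domain."""


class InvalidParameterError(VitalReconError, ValueError):
    """A kernel parameter set violates its invariants (e.g. spread <= 0)."""


class DataSchemaError(VitalReconError, ValueError):
    """An input file does not match the expected schema."""


class MeshMismatchError(VitalReconError, ValueError):
    """Two objects defined on different size meshes were combined."""


class ConvergenceError(VitalReconError, RuntimeError):
    """An iterative numerical routine failed to converge.

    Carries the final residual for diagnostics.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
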