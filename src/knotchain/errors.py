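"""Exception hierarchy shared across the package."""


class KnotchainError(Exception):
    """Base class for all package-specific errors."""


class OverstretchedBondError(KnotchainError):
    """A FENE bond reached or exceeded its maximum extension R0.

    This signals a potential topology-safety violation: once a bond can
    stretch past R0, chain strands may cross and the knot type is no
    longer conserved.
    """


class DegenerateGeometryError(KnotchainError):
    """Zero-length bond or otherwise degenerate conformation geometry."""


class TopologySafetyError(KnotchainError):
    """The integrator detected a state in which topology conservation
    can no longer be guaranteed."""


class InstabilityError(KnotchainError):
    """Numerical instability (NaN/inf positions); try a smaller timestep."""


class WrongTopologyError(KnotchainError):
    """An operation received a chain whose closure has an unexpected
    knot type."""


class ProjectionError(KnotchainError):
    """No generic planar projection found within the retry budget."""


class ParseError(KnotchainError):
    """Malformed trajectory or table file."""
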