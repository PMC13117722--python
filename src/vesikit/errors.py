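"""Exception hierarchy for vesikit."""


class VesikitError(Exception):
    """Base class for all vesikit errors."""


class UnknownLipidError(VesikitError, KeyError):
    """Requested lipid species is not in the packaged registry."""


class MissingParameterError(VesikitError, KeyError):
    """A nonbonded pair is absent from the parameter table."""


class DomainError(VesikitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class BuildError(VesikitError):
    """The requested vesicle geometry cannot be realised."""


class CapacityError(BuildError):
    """A requested water count exceeds the solvation lattice capacity."""

    def __init__(self, requested: int, capacity: int, region: str):
        self.requested = requested
        self.capacity = capacity
        self.region = region
        super().__init__(
            f"requested {requested} water beads in the {region} region but the "
            f"lattice holds at most {capacity}"
        )


class ConsistencyError(VesikitError):
    """Internal bookkeeping disagrees (labels, group names, provenance)."""


class TrajectoryMismatchError(VesikitError):
    """Structure and trajectory files disagree on the particle count."""


class ResolutionError(VesikitError, ValueError):
    """Pore-grid resolution is incompatible with the lipid spacing."""


class SingularGeometryError(VesikitError, ValueError):
    """A geometric computation hit a degenerate configuration (zero-length vector)."""


class SamplerFailureError(VesikitError, RuntimeError):
    """Rejection sampling acceptance fell below the usable floor."""
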