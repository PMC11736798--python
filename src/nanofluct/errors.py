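"""Exception hierarchy for nanofluct."""


class NanofluctError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(NanofluctError, ValueError):
    """Thermodynamic state outside the model's physical domain."""


class UnsupportedModelError(NanofluctError, ValueError):
    """Operation requested for a dimension/model it does not support."""


class ParameterError(NanofluctError, ValueError):
    """A parameter is outside its admissible range."""


class TruncationError(NanofluctError, ValueError):
    """Requested range exceeds what the implemented expansion can cover."""


class CoverageError(NanofluctError, ValueError):
    """A subvolume size exceeds the tabulated range of the input RDF."""


class RDFFormatError(NanofluctError, ValueError):
    """Malformed tabulated-RDF text file."""


class FitError(NanofluctError, ValueError):
    """Asymptote fit cannot be performed (too few points)."""


class PackingError(NanofluctError, ValueError):
    """Particle number incompatible with the simulation box."""


class DoubleModificationError(NanofluctError, ValueError):
    """Attempt to apply the excluded-volume convolution twice."""
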