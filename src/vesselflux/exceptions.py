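"""Exception hierarchy for vesselflux."""


class VesselfluxError(Exception):
    """Base class for all vesselflux errors."""


class ParameterError(VesselfluxError, ValueError):
    """A physical or configuration parameter is invalid."""


class GenerationError(VesselfluxError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class FitError(VesselfluxError, RuntimeError):
    """A regression or model fit could not be performed."""


class NetworkError(VesselfluxError, ValueError):
    """A metabolic network violates a structural invariant."""


class ConstraintError(VesselfluxError, ValueError):
    """Measured-rate constraints cannot be mapped onto the network."""


class PipelineError(VesselfluxError, RuntimeError):
    """A pipeline stage failed or was misconfigured."""
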