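"""Exception hierarchy for the pathway-GWAS pipeline."""


class PathgwasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PathgwasError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(PathgwasError):
    """The synthetic-data generator could not satisfy the request."""


class ParseError(PathgwasError):
    """Malformed input file; message carries the offending line number."""


class PipelineError(PathgwasError):
    """A pipeline stage received no usable data."""


class DegenerateSetError(PathgwasError):
    """A gene set is empty, spans the whole ranked list, or has zero total weight."""
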