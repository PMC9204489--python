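"""Exception hierarchy shared across the pipeline.

Validation errors cover malformed inputs and configuration (CLI exit code 2);
analysis errors cover conditions detected mid-computation, such as a protein
set that is empty after restriction to the network (exit code 3).
"""


class NetproxError(Exception):
    """Base class for all package errors."""


class ValidationError(NetproxError):
    """Malformed input data, file, or configuration."""


class AnalysisError(NetproxError):
    """A computation cannot proceed on otherwise well-formed inputs."""
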