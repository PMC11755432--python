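"""Exception hierarchy shared across the package."""


class McqsarError(Exception):
    """Base class for all package errors."""


class MalformedInputError(McqsarError):
    """A SMILES string cannot be tokenized (e.g. unbalanced bracket)."""


class ConfigurationError(McqsarError):
    """Invalid run configuration or mismatched inputs."""


class UndefinedStatisticError(McqsarError):
    """A statistic is undefined for the given vectors (constant input, r2=1 for F, ...)."""


class DegenerateFitError(McqsarError):
    """Least-squares fit is degenerate (constant descriptor or endpoint)."""


class TransformError(McqsarError):
    """Endpoint transform cannot be applied (non-positive value, double transform)."""


class SchemaError(McqsarError):
    """An input file does not match the expected schema."""


class SplitError(McqsarError):
    """Dataset too small or otherwise unsplittable into four sets."""
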