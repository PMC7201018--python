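"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`GofuseError` so the
CLI can map them onto exit codes without catching bare ``Exception``.
"""


class GofuseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GofuseError):
    """A file is structurally malformed (empty FASTA, wrong column count...)."""


class ValidationError(GofuseError):
    """A parsed value violates a domain invariant (duplicate id, bad score...)."""


class ConfigurationError(GofuseError):
    """A configuration value is inconsistent or makes the task degenerate."""


class ShapeError(GofuseError):
    """An array input does not have the shape a model expects."""


class EvaluationError(GofuseError):
    """Evaluation is impossible (no positive labels, disjoint protein sets...)."""


class TrainingError(GofuseError):
    """Training diverged or an internal training invariant was broken."""
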