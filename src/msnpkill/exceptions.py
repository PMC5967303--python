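"""Exception taxonomy for the analysis pipeline.

Error classes map to distinct failure modes so the CLI can translate them
into exit codes (configuration errors exit 2, computation errors exit 1).
"""


class MsnpKillError(Exception):
    """Base class for all package errors."""


class FormatError(MsnpKillError):
    """A table or config file is structurally malformed (e.g. missing column)."""


class ValidationError(MsnpKillError):
    """A value violates a type invariant (e.g. non-positive tumor volume)."""


class DomainError(MsnpKillError):
    """Inputs are well-formed but outside an operation's domain
    (e.g. onset day not shared by both series, too few points to fit)."""


class QuantificationError(MsnpKillError):
    """A standard-additions curve cannot yield a concentration
    (e.g. non-positive fitted slope)."""


class GenerationError(MsnpKillError):
    """A synthetic cohort spec produced physically impossible data."""


class ConfigurationError(MsnpKillError):
    """A run configuration is unusable before any computation starts."""
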