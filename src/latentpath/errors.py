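"""Exception hierarchy shared across the package."""


class LatentPathError(Exception):
    """Base class for all package errors."""


class DimensionError(LatentPathError):
    """Latent-vector dimensions or parts do not match."""


class StructureError(LatentPathError):
    """Input string does not parse as a structure for the backend."""


class UnsupportedCompoundError(StructureError):
    """Structure parses but lies outside the backend's supported universe."""


class CapabilityError(LatentPathError):
    """Backend asked to perform an operation it does not support (e.g. decode)."""


class ParameterError(LatentPathError):
    """Invalid or infeasible parameter value."""


class FormatError(LatentPathError):
    """Malformed serialized file (missing columns/fields, bad schema)."""


class EmptyDatabaseError(LatentPathError):
    """No usable records remain to build a reaction-feature DB."""


class ClassError(LatentPathError):
    """Fewer than two eligible classes for classification."""


class ScoringError(LatentPathError):
    """Candidate pathway cannot be scored (missing segment substrates)."""


class ConfigurationError(LatentPathError):
    """Run configuration is missing a required field."""
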