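"""Exception hierarchy for the RESCAN pipeline."""


class RescanError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(RescanError, ValueError):
    """A parameter is outside its documented range."""


class IncompatibleReferenceError(RescanError):
    """Two genomes that must share a coordinate frame do not."""


class ConfigurationError(RescanError):
    """A library design or pipeline configuration is internally inconsistent."""


class DependencyError(RescanError, FileNotFoundError):
    """A pipeline stage is missing an upstream artifact; names the file."""


class DataIntegrityError(RescanError):
    """Inputs disagree where they must agree (e.g. reference base conflicts)."""


class UndefinedStatisticError(RescanError, ZeroDivisionError):
    """A requested statistic has an empty denominator."""
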