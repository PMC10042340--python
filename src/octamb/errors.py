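"""Package-wide exception types."""


class OctambError(Exception):
    """Base class for all octamb errors."""


class ValidationError(OctambError, ValueError):
    """A configuration, specification or array failed its invariants."""


class FormatError(OctambError, ValueError):
    """An input file could not be parsed in a supported format."""


class TrainingError(OctambError, RuntimeError):
    """Training diverged or was invoked with unusable inputs."""
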