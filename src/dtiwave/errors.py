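"""Exception hierarchy shared across the pipeline."""


class DtiwaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DtiwaveError):
    """A configuration value or table has the wrong shape/type."""


class InputError(DtiwaveError):
    """User-supplied data is unusable (empty sequence, empty molecule, ...)."""


class ParseError(DtiwaveError):
    """A file or record could not be parsed."""


class DegenerateScaleError(DtiwaveError):
    """A zero-variance column cannot be z-scored."""


class TooShortError(DtiwaveError):
    """Signal too short for the requested decomposition depth."""

    def __init__(self, length: int, levels: int, min_length: int):
        self.length = length
        self.levels = levels
        self.min_length = min_length
        super().__init__(
            f"signal of length {length} does not admit {levels} decomposition "
            f"level(s); minimum length is {min_length}"
        )


class UnknownIDError(DtiwaveError, KeyError):
    """Drug or target ID absent from the network registries."""
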