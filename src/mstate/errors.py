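"""Exception hierarchy shared across the package."""


class MstateError(Exception):
    """Base class for package errors."""


class ParameterError(MstateError, ValueError):
    """Invalid argument or configuration value."""


class FormatError(MstateError, ValueError):
    """A file does not conform to the declared dialect."""


class DegenerateMapError(MstateError, ValueError):
    """A topography has zero field power where a non-degenerate map is required."""


class ChannelLookupError(MstateError, KeyError):
    """A requested electrode label is not present in the recording."""
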