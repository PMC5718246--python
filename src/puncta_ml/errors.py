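"""Exception hierarchy shared across the pipeline."""


class PunctaError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PunctaError):
    """A file is missing, unreadable, or not a supported image."""


class ConfigError(PunctaError):
    """A configuration value is out of range or inconsistent."""


class UnsupportedInputError(InputError):
    """The file is a recognized image but not one this tool processes (e.g. a Z-stack)."""


class EmptyDatasetError(InputError):
    """Dataset discovery found no images at all."""


class DegenerateDataError(PunctaError):
    """A statistical routine received data with no usable variance."""


class UndefinedObjectiveError(PunctaError):
    """A trace objective was requested on an empty edge image."""
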