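"""Exception types shared across the pipeline."""


class ScregulonError(Exception):
    """Base class for all package errors."""


class ConfigError(ScregulonError, ValueError):
    """Invalid configuration or parameter values."""


class InputError(ScregulonError, ValueError):
    """Invalid input data (empty matrices, mismatched labels, bad groups)."""


class EmptyResultError(ScregulonError, ValueError):
    """An operation removed everything; silent empty output is never returned."""


class FormatError(ScregulonError, ValueError):
    """A file on disk is malformed; the message names the file."""
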