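"""Exception hierarchy shared across the pipeline."""


class PqtlmrError(Exception):
    """Base class for all package errors."""


class ConfigError(PqtlmrError):
    """A configuration problem: missing column mapping, bad threshold, unknown key."""


class InputError(PqtlmrError):
    """An input-data problem: empty file, empty variant intersection, unreadable path."""
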