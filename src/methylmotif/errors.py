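"""Exception hierarchy shared across the package."""


class MethylMotifError(Exception):
    """Base class for all package errors."""


class DataError(MethylMotifError):
    """Malformed or inconsistent input data (CLI exit code 2)."""
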