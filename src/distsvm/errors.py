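"""Exception types shared across the package."""


class DistSVMError(Exception):
    """Base class for package errors."""


class FormatError(DistSVMError, ValueError):
    """A file did not match the expected format."""
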