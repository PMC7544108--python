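"""Shared exception types."""


class OtomapError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(OtomapError, ValueError):
    """An argument violates a documented precondition."""


class AlignmentError(OtomapError):
    """Two inputs that must share a variant/gene universe do not."""


class MissingLDError(OtomapError, KeyError):
    """LD was requested for a pair the provider cannot supply."""
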