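"""Shared exception types."""


class NarrascreenError(Exception):
    """Base class for all package errors."""


class ValidationError(NarrascreenError, ValueError):
    """Invalid input data or configuration."""


class BackendError(NarrascreenError, RuntimeError):
    """A remote (or mocked remote) backend failed.

    ``failed_indices`` carries the positions of the inputs whose requests
    failed, so callers can retry just those.
    """

    def __init__(self, message: str, failed_indices: tuple[int, ...] = ()):
        super().__init__(message)
        self.failed_indices = failed_indices
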