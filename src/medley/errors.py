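"""Exception hierarchy shared across the pipeline stages."""


class MedleyError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedleyError):
    """Input data violated a structural invariant (exit code 2 at the CLI)."""


class DependencyError(MedleyError):
    """A pipeline stage was requested without its upstream artifact (exit code 3)."""


class SynthesizerExhaustedError(MedleyError):
    """Every synthesizer in the failover chain failed (exit code 4).

    Carries the complete attempt log so the failure can be audited.
    """

    def __init__(self, message: str, attempt_log: list):
        super().__init__(message)
        self.attempt_log = attempt_log
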