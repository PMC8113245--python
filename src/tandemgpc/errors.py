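"""Exception types shared across the package."""


class TandemGPCError(Exception):
    """Base class for all package errors."""


class DesignValidationError(TandemGPCError):
    """Raised when a circuit design fails validation.

    Carries the full list of violations so callers can report all
    problems at once rather than one per run.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid circuit design:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class NoMoreStages(TandemGPCError):
    """Raised when excision is requested on a construct with no GPC left."""


class UnsupportedVersion(TandemGPCError):
    """Raised for operations defined only for one circuit architecture version."""


class AmbiguousPrimer(TandemGPCError):
    """Raised when a PCR primer is absent or maps to multiple positions."""


class PresetError(TandemGPCError):
    """Raised for unknown preset names; lists the available presets."""
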