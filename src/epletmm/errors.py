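"""Exception hierarchy shared across the package."""


class EpletMMError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EpletMMError):
    """A tabular input row could not be parsed."""


class ValidationError(EpletMMError):
    """An in-memory value violates a structural invariant."""


class ImputationError(EpletMMError):
    """No haplotype pair is compatible with the observed typing."""


class RegistryLookupError(EpletMMError):
    """An allele is absent from the eplet registry."""


class ContractError(EpletMMError):
    """An operation was called with arguments outside its contract."""


class DerivationError(EpletMMError):
    """Cohort-specific threshold derivation failed (e.g. no events left)."""


class CoxError(EpletMMError):
    """Proportional-hazards fitting failed to converge."""


class PipelineError(EpletMMError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
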