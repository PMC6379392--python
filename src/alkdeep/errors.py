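"""Exception types shared across the pipeline."""


class AlkDeepError(Exception):
    """Base class for all package errors."""


class FrameUnknownError(AlkDeepError):
    """A genomic position lies outside the inferable coding frame."""


class ReferenceMismatchError(AlkDeepError):
    """A stated reference base disagrees with the bundled reference."""


class OutOfTargetError(AlkDeepError):
    """A genomic position falls outside every target region."""


class TooFewControlsError(AlkDeepError):
    """Background estimation needs at least two control samples."""


class ModelCoverageError(AlkDeepError):
    """The noise model does not cover a requested (position, alt) pair."""


class UndefinedFrequencyError(AlkDeepError):
    """Allele frequencies are undefined at zero depth."""


class InvalidConfigurationError(AlkDeepError):
    """A simulation or run configuration is internally inconsistent."""


class EmptyModelError(AlkDeepError):
    """Control pileups share no positions with the target regions."""


class UndefinedTestError(AlkDeepError):
    """A statistical test is undefined for the given inputs (e.g. no events)."""
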