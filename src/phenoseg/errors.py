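"""Exception types shared across the pipeline."""


class PhenosegError(Exception):
    """Base class for all package-specific errors."""


class MissingTargetError(PhenosegError):
    """No usable target object (detection, mask, or landmark support) was found.

    Raised when an image yields no detection of the wanted class, or when a
    mask is too small/empty to phenotype.  Pipeline drivers catch this and
    record the image as failed instead of aborting the batch.
    """


class BackendUnavailableError(PhenosegError):
    """A detector backend was requested that is not usable in this installation."""


class InvalidSpecError(PhenosegError):
    """A synthetic-fixture or configuration spec violates its invariants."""


class PedigreeError(PhenosegError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""
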