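"""Exception types raised across the package."""


class ToxprioError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdentifierError(ToxprioError):
    """A chemical identifier occurs more than once in one table."""


class TableMismatchError(ToxprioError):
    """Tables that must share chemicals/descriptors do not."""


class CurationError(ToxprioError):
    """A descriptor-curation step failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class NotFittedError(ToxprioError):
    """A model or categorizer was used before being fitted."""


class ValidationError(ToxprioError):
    """A run configuration failed validation; carries itemized problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
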