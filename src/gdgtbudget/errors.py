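"""Exception hierarchy shared across the package."""


class GdgtBudgetError(Exception):
    """Base class for all package errors."""


class ConfigError(GdgtBudgetError):
    """Invalid configuration (bad parameter value, missing file, malformed config)."""


class DataError(GdgtBudgetError):
    """Invalid or inconsistent input data (duplicate keys, mixed samples, bad values)."""


class UndefinedResultError(GdgtBudgetError):
    """A requested quantity is mathematically undefined for the given input.

    Raised instead of silently returning 0 (e.g. TEX86 with a zero denominator,
    attribution when all expected pools are zero, a Mantel correlation against
    a constant matrix).
    """


class StageError(GdgtBudgetError):
    """A pipeline stage failed; carries the stage name and offending sample."""

    def __init__(self, stage: str, message: str, sample_id: str | None = None):
        self.stage = stage
        self.sample_id = sample_id
        where = f"stage '{stage}'" + (f", sample '{sample_id}'" if sample_id else "")
        super().__init__(f"{where}: {message}")
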