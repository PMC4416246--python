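"""Exception hierarchy.

Everything user-facing derives from :class:`IfnScoreError` so callers (and the
CLI) can catch one type.
"""


class IfnScoreError(ValueError):
    """Base class for all ifnscore errors."""


class ExpressionError(IfnScoreError):
    """Malformed or inconsistent expression input."""


class ScoringError(IfnScoreError):
    """Gene-set score cannot be computed."""


class ClinicalError(IfnScoreError):
    """Malformed clinical table or invalid statistical request."""


class PredictionError(IfnScoreError):
    """ROC / cut-off analysis cannot be performed."""


class ConfigError(IfnScoreError):
    """Invalid simulation or run configuration."""
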