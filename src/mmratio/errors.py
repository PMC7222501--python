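"""Exception hierarchy.

All package errors derive from :class:`MMRatioError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class MMRatioError(Exception):
    """Base class for all mmratio errors."""


class SchemaError(MMRatioError):
    """An input table is missing a registered column."""


class ValidationError(MMRatioError):
    """A value violates its declared bounds or type."""


class ConfigurationError(MMRatioError):
    """A registry / simulation config is malformed or inconsistent."""


class EstimationError(MMRatioError):
    """A model fit failed (rank deficiency, separation, non-convergence, n too small)."""


class DegenerateInputError(MMRatioError):
    """An input has no variance or is otherwise degenerate for the operation."""


class ContractViolationError(MMRatioError):
    """A model comparison violates the marginality convention."""
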