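"""Named exception classes for input validation and engine failures.

Every malformed input is rejected with a distinct error class carrying the
offending coordinates (year, category, column, ...) so that validation
failures in large ratio tables can be located without a debugger.
"""

from __future__ import annotations


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class MissingYearError(ValidationError):
    """A required year is absent (gap in a series or table)."""


class RatioSumError(ValidationError):
    """Fractions for one (year, source) do not sum to 1 within tolerance."""


class UnknownFateError(ValidationError):
    """A discard-fate label is not one of the six recognised fates."""


class NegativeValueError(ValidationError):
    """A mass, fraction or half-life is negative where it may not be."""


class MissingParameterError(ValidationError):
    """A category encountered during simulation has no parameter row."""


class UnknownScenarioError(ValidationError):
    """Scenario name is not one of the recognised scenario strings."""


class UnknownCategoryError(ValidationError):
    """A fixed-carbon override names a category absent from the run."""


class AmbiguousCrosswalkError(ValidationError):
    """Two crosswalk rules of equal priority match one end use."""


class AllZeroYearError(ValidationError):
    """A waste-characterisation year has zero total tonnage (undefined ratios)."""


class EngineError(RuntimeError):
    """Non-finite state encountered during simulation (fail fast)."""
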