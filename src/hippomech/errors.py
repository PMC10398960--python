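"""Exception hierarchy for the hippomech pipeline.

Every stage raises a subclass of :class:`HippomechError` so that the
pipeline driver can tag failures with the stage that produced them.
"""


class HippomechError(Exception):
    """Base class for all hippomech errors."""


class ParameterError(HippomechError, ValueError):
    """A physical or configuration parameter violates its constraints."""


class ConfigurationError(HippomechError, KeyError):
    """A cohort/region key or pipeline config entry is unknown or missing."""


class InsufficientBaselineError(HippomechError, ValueError):
    """Too few pre-contact samples to fit a deflection baseline."""


class NoContactError(HippomechError, ValueError):
    """No tip-sample contact detectable in a force-distance curve."""


class FitError(HippomechError, RuntimeError):
    """A Hertz fit could not be performed (e.g. too few samples)."""


class DomainError(HippomechError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class AlignmentError(HippomechError, ValueError):
    """Grid/mask shapes or coordinates do not line up."""


class DuplicatePositionError(HippomechError, ValueError):
    """Two indentation results map to the same grid cell."""


class LabelError(HippomechError, ValueError):
    """A subregion label is outside the valid 1-10 range."""


class RenderError(HippomechError, ValueError):
    """A map or heatmap cannot be rendered (e.g. no data)."""


class AggregationError(HippomechError, ValueError):
    """ROI aggregation received empty or inconsistent input."""


class StageError(HippomechError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
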