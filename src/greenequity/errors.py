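"""Exception hierarchy for the greenequity pipeline."""


class GreenEquityError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GreenEquityError):
    """A city or scenario configuration violates its invariants."""


class GridAlignmentError(GreenEquityError):
    """Two grids do not nest or align as an operation requires."""


class SamplingError(GreenEquityError):
    """A point falls outside the extent of the raster being sampled."""


class DisaggregationError(GreenEquityError):
    """Zone-to-building disaggregation is undefined (e.g. zero zone population)."""


class UndefinedExposureError(GreenEquityError):
    """A weighted mean was requested for an absent subgroup (zero total weight)."""


class SingleClassError(GreenEquityError):
    """Income quintile classification is undefined (all zone incomes identical)."""


class ZoneCoverageError(GreenEquityError):
    """A zone polygon contains no raster cell centers."""


class ReportError(GreenEquityError):
    """An exposure table lacks rows the report requires."""
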