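"""Exception hierarchy.

Configuration problems (bad column maps, bad thresholds) are distinguished from
row-level data validation and from analysis-level failures (too few usable
instruments, empty harmonization intersections) so that a pipeline run can skip
a failed exposure-outcome pair without masking a broken config.
"""


class MrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrError):
    """Invalid configuration: missing columns, bad thresholds, unreadable files."""


class ValidationError(MrError):
    """A record or table violates a data invariant (e.g. se <= 0, bad allele)."""


class AnalysisError(MrError):
    """An analysis cannot proceed (too few instruments, empty intersection)."""


class DegenerateInstrumentError(AnalysisError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""
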