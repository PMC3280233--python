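"""Exception hierarchy shared across the pipeline."""


class SubwrapError(Exception):
    """Base class for all package errors."""


class FormatError(SubwrapError):
    """Malformed input file (empty, unparseable, ragged, duplicate ids)."""


class StructureError(SubwrapError):
    """A structure lacks the protein content needed for analysis."""


class DataError(SubwrapError):
    """A required datum (atom, column, family member) is missing."""


class SequenceError(SubwrapError):
    """Invalid coding sequence (internal stop, bad alphabet, bad length)."""


class SaturationError(SubwrapError):
    """Synonymous divergence beyond the correctable range (p_s >= 3/4)."""


class UndefinedStatisticError(SubwrapError):
    """A ratio or correlation has no defined value (zero denominator)."""


class SpecError(SubwrapError):
    """Infeasible or invalid simulation specification."""


class AnalysisError(SubwrapError):
    """Statistical step cannot run (degenerate design, too few records)."""


class PipelineError(SubwrapError):
    """Orchestration failure; carries the failing stage name."""
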