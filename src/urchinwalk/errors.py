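"""Exception hierarchy for trajectory validation and analysis."""


class UrchinwalkError(Exception):
    """Base class for all package errors."""


class FormatError(UrchinwalkError):
    """Input file does not conform to the expected tabular layout."""


class IntegrityError(UrchinwalkError):
    """Data violate a trajectory invariant (duplicates, gaps, non-finite)."""


class InsufficientDataError(UrchinwalkError):
    """Too few positions/steps/observations for the requested quantity."""


class UndefinedHeadingError(UrchinwalkError):
    """A heading vector has zero length, so its angle is undefined."""
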