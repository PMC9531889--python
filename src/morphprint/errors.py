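"""Exception hierarchy for the morphprint pipeline.

Validation problems (bad files, unknown regions, inconsistent demographics)
raise :class:`ValidationError` subclasses; statistical degeneracies (zero
variance, rank deficiency) raise :class:`DegenerateStatisticsError`
subclasses.  The CLI maps the two families onto distinct exit codes.
"""


class MorphprintError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MorphprintError):
    """Input data violates a structural contract."""


class ParseError(ValidationError):
    """A flat file could not be parsed; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class UnknownRegionError(ValidationError):
    """A region label does not resolve against the registry."""

    def __init__(self, name: str, candidates: list[str] | None = None):
        hint = ""
        if candidates:
            hint = f"; nearest matches: {', '.join(candidates)}"
        super().__init__(f"unknown region {name!r}{hint}")
        self.name = name
        self.candidates = candidates or []


class DuplicateKeyError(ValidationError):
    """The same (subject, region, hemisphere, metric) appeared twice."""


class InconsistentDemographicsError(ValidationError):
    """A subject's demographic fields disagree between rows or files."""


class ReconciliationError(ValidationError):
    """Subjects in stats files and demographics table do not match up."""


class MissingICVError(ValidationError):
    """An aseg.stats file lacks the EstimatedTotalIntraCranialVol measure."""


class MissingDataError(ValidationError):
    """A required measurement or model key is absent."""


class ProvenanceError(ValidationError):
    """A table is at the wrong pipeline stage for the requested operation."""


class DegenerateStatisticsError(MorphprintError):
    """A statistic cannot be computed (zero variance, too few subjects...)."""


class DegenerateReferenceError(DegenerateStatisticsError):
    """Control reference SD is zero for some key."""
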