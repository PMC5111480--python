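"""Exception hierarchy for contour validation and analysis errors."""


class CineLVError(ValueError):
    """Base class for all domain errors raised by this package."""


class DegeneratePolygonError(CineLVError):
    """Polygon has fewer than 3 vertices or consecutive duplicate vertices."""


class InvalidPolygonError(CineLVError):
    """Polygon is self-intersecting (not simple)."""


class ArcIndexError(CineLVError):
    """Infarct arc index range is out of bounds or arcs overlap."""


class PairingError(CineLVError):
    """Epicardial/endocardial tracings are missing or inconsistent for a
    (slice, phase), or the endocardial area is not strictly smaller than the
    epicardial area."""


class StudyStructureError(CineLVError):
    """Slice/phase indexing of a study violates contiguity or uniformity."""


class ContourParseError(CineLVError):
    """Malformed contour file row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PhaseError(CineLVError):
    """Requested cardiac phase does not exist in the study."""


class InfarctMarkingError(CineLVError):
    """Infarct arcs are marked only on non-end-diastolic phases."""


class UndefinedCorrelationError(CineLVError):
    """Correlation is undefined (constant column or too few rows)."""


class CohortSchemaError(CineLVError):
    """Cohort table violates the expected schema or invariants."""


class SpecError(CineLVError):
    """A synthetic-data spec describes impossible geometry or physiology."""
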