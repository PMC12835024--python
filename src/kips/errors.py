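"""Exception hierarchy shared across the package."""


class KipsError(Exception):
    """Base class for all package errors."""


class FhirParseError(KipsError):
    """Malformed FHIR JSON; carries the byte offset of the defect when known."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


class UnsupportedResourceError(KipsError):
    """resourceType missing or not in the registered set."""


class PathNotFoundError(KipsError):
    """A dotted element path does not address an existing element."""


class InvalidArgumentError(KipsError):
    """An argument violates an operation precondition."""


class RegistryError(KipsError):
    """Gap registry file malformed, missing, or degenerate."""


class ConceptMapError(KipsError):
    """Concept-map CSV malformed (duplicate key, missing column)."""


class TransformError(KipsError):
    """Base for transformation failures."""


class TransformTypeError(TransformError):
    """Resource routed to a rule-set for a different resourceType."""


class ExtractionError(TransformError):
    """A required contained resource could not be extracted."""


class MissingIdError(TransformError):
    """A reference target id could not be recovered for flattening."""


class MissingElementError(TransformError):
    """A mandatory element could not be populated (strict mode)."""


class MappingError(TransformError):
    """A local code has no entry in the concept map (strict mode)."""


class ValidationTypeError(KipsError):
    """Profile validation requested for an unsupported resourceType."""


class PipelineError(KipsError):
    """ETL pipeline configuration or I/O failure."""
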