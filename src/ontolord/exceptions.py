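"""Exception hierarchy shared across the package."""


class OntolordError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OntolordError, ValueError):
    """A serialized table row could not be parsed.

    Carries the offending file name and 1-based line number.
    """

    def __init__(self, message: str, *, filename: str | None = None, line: int | None = None):
        self.filename = filename
        self.line = line
        prefix = ""
        if filename is not None:
            prefix = f"{filename}:{line}: " if line is not None else f"{filename}: "
        super().__init__(prefix + message)


class ValidationError(OntolordError, ValueError):
    """A loaded object violates a structural invariant."""


class TemplateError(OntolordError, KeyError):
    """No verbalization template is available for a relation predicate."""


class SamplingError(OntolordError, ValueError):
    """A batch cannot be sampled under the requested constraints."""


class InputError(OntolordError, ValueError):
    """An operation received invalid inputs (bad norms, missing keys, ...)."""


class ConfigurationError(OntolordError, ValueError):
    """An operation was configured inconsistently."""


class IncompatibilityError(OntolordError, ValueError):
    """Parameter snapshots cannot be averaged together."""


class MappingError(OntolordError, KeyError):
    """A character falls outside a cipher's alphabet."""


class UndefinedCorrelationError(OntolordError, ValueError):
    """A correlation is undefined because one score series has zero variance."""
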