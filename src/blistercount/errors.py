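"""Exception hierarchy for the blister pipeline."""


class BlisterCountError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(BlisterCountError, ValueError):
    """A filter or pipeline parameter violates its precondition."""


class BlisterNotFoundError(BlisterCountError):
    """Automatic blister detection found no foreground component.

    Callers are expected to fall back to a manual crop.
    """


class ImageTooSmallError(BlisterCountError, ValueError):
    """Crop is too small to be a plausible blister photograph."""


class RegistrationFailedError(BlisterCountError):
    """No pill circles survived detection/artifact rejection."""


class IncompatibleReferenceError(BlisterCountError):
    """Counting-mode image geometry does not match the stored reference."""


class InvalidSpecError(BlisterCountError, ValueError):
    """A synthetic blister specification is geometrically infeasible."""


class ReferenceNotFoundError(BlisterCountError, KeyError):
    """Requested blister id is absent from the reference store."""


class ReferenceConflictError(BlisterCountError):
    """Blister id already registered and overwrite was not requested."""


class StoreParseError(BlisterCountError):
    """Reference store file exists but cannot be parsed."""


class SchemaVersionError(BlisterCountError):
    """Reference store schema version is not supported."""
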