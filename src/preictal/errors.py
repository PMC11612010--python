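"""Exception hierarchy shared across the package."""


class PreictalError(Exception):
    """Base class for all package-specific errors."""


class EDFReadError(PreictalError, IOError):
    """Raised when an EDF file cannot be read."""


class MontageError(PreictalError):
    """Channel set or channel order does not match what an operation needs."""


class UnrecoverableDataError(PreictalError):
    """All channels failed quality control; nothing left to interpolate from."""


class ParameterError(PreictalError, ValueError):
    """An operation was called with an out-of-range parameter."""


class LengthError(PreictalError, ValueError):
    """Input sequence or signal too short for the requested computation."""


class DegenerateInputError(PreictalError, ValueError):
    """Input has no variance (or otherwise no information) where some is required."""


class SpecError(PreictalError, ValueError):
    """Invalid synthetic-data specification."""


class StratificationError(PreictalError, ValueError):
    """A train/test split would leave one class empty."""


class FeatureAssemblyError(PreictalError, ValueError):
    """A requested feature family or value is missing for some epoch."""


class DataCompletenessError(PreictalError, ValueError):
    """A subject is missing one of the two groups required for a paired table."""
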