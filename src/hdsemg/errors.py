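"""Exception hierarchy shared across the pipeline stages."""


class HdsemgError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HdsemgError, ValueError):
    """An argument is outside its documented domain."""


class SchemaError(HdsemgError, ValueError):
    """A session record violates the deposited variable schema."""


class WindowError(HdsemgError, ValueError):
    """An analysis window falls outside the recorded span."""


class AlignmentError(HdsemgError, ValueError):
    """Streams cannot be aligned (e.g. no synchronization pulses found)."""


class AssemblyError(HdsemgError, ValueError):
    """Session components have inconsistent durations or provenance."""


class LayoutError(HdsemgError, ValueError):
    """An electrode-grid layout is not a bijection onto channel indices."""


class TableError(HdsemgError, ValueError):
    """A movement/DoF lookup table is malformed or breaks catalogue rules."""


class LabelLookupError(HdsemgError, KeyError):
    """A movement code has no row in the lookup table."""


class DegeneratePoolError(HdsemgError, ValueError):
    """Too few eligible channels to form outlier-score quartiles."""
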