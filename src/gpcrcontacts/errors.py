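"""Exception hierarchy shared across the pipeline stages."""


class GpcrContactsError(Exception):
    """Base class for all package errors."""


class FormatError(GpcrContactsError):
    """A file could not be parsed in its declared format."""


class SelectionError(GpcrContactsError):
    """A residue selection is empty or otherwise unusable."""


class TopologyError(GpcrContactsError):
    """Trajectory frames are inconsistent with the topology."""


class RangeError(GpcrContactsError):
    """A frame window selects no frames."""


class ValidationError(GpcrContactsError):
    """Tabular input violates its schema or controlled vocabulary."""


class ConfigurationError(GpcrContactsError):
    """Criteria / run configuration is incomplete or inconsistent."""


class DataError(GpcrContactsError):
    """A computation received structurally valid but empty/unusable data."""


class ParameterError(GpcrContactsError):
    """A user parameter is outside its meaningful range."""


class AlignmentError(GpcrContactsError):
    """Two artifacts that must share a contact-pair universe do not."""


class DegenerateModelError(GpcrContactsError):
    """The discriminant model cannot be fit (too few classes or rank)."""


class SplitError(GpcrContactsError):
    """A train/test split left some class unrepresented in training."""


class GenerationError(GpcrContactsError):
    """Synthetic structure generation produced invalid geometry."""
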