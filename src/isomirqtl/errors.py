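"""Exception types shared across the pipeline stages."""


class IsomirQTLError(Exception):
    """Base class for package errors."""


class ConfigurationError(IsomirQTLError, ValueError):
    """An invalid simulation or pipeline configuration; names the offending field."""


class InputError(IsomirQTLError, ValueError):
    """Malformed input data (bad characters, bad records)."""


class GenerationError(IsomirQTLError, ValueError):
    """A requested synthetic isomiR label cannot be realised on its precursor."""


class ClassificationError(IsomirQTLError, ValueError):
    """An alignment violates the invariants the classifier relies on."""


class ConsistencyError(IsomirQTLError, ValueError):
    """Cross-file disagreement, e.g. a VCF REF base not matching the precursor."""


class DegenerateDataError(IsomirQTLError, ValueError):
    """A statistic is undefined on the given data (constant vector, empty group)."""
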