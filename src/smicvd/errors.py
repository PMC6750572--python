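"""Exception hierarchy shared across the pipeline stages."""


class SmicvdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmicvdError):
    """Invalid simulation or pipeline configuration; message names the field."""


class SpecificationError(SmicvdError):
    """Invalid risk-equation specification (unknown predictor, bad baseline survival ...)."""


class ScoringError(SmicvdError):
    """A record could not be scored; message identifies person and predictor."""


class DataError(SmicvdError):
    """Malformed input table (null required fields, negative times ...)."""


class LinkageError(SmicvdError):
    """A contact references a person id absent from the person table."""


class ExtrapolationWarning(UserWarning):
    """Risk queried beyond the last observed follow-up time."""
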