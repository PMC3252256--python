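"""Exception types shared across the package."""


class WardstockError(Exception):
    """Base class for all package errors."""


class ValidationError(WardstockError):
    """An input value violates a documented precondition."""


class UnknownAgentError(WardstockError, KeyError):
    """A record refers to an agent_id absent from the DDD reference table."""


class SequencingError(WardstockError):
    """Stock snapshots are not consecutive or belong to different wards."""


class ConfigurationError(WardstockError):
    """A run configuration is internally inconsistent (e.g. interval length
    does not divide the retained study weeks)."""


class InsufficientDataError(WardstockError):
    """Too few paired registrations for the requested statistic."""


class DegenerateDataError(WardstockError):
    """All observations identical (zero total variance); the statistic is
    undefined rather than zero or one."""
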