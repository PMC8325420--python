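"""Exception hierarchy for the monitoring toolkit."""


class TrialmonError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(TrialmonError):
    """A CSV file does not match the documented interchange schema."""


class IntegrityError(TrialmonError):
    """A record references a participant or variable that does not exist."""


class DataParseError(TrialmonError):
    """A field could not be parsed; the message carries the row number."""


class ConfigError(TrialmonError):
    """An invalid configuration value or a missing variable mapping."""


class InsufficientCentresError(TrialmonError):
    """Fewer than three centres survive the exclusion rules; a distance
    to a common mean of so few points is meaningless."""


class DegenerateModelError(TrialmonError):
    """Every candidate feature has zero across-centre variance."""


class BlindingError(TrialmonError):
    """A centre is missing from the blinding map; rendering refuses to
    fall back to the raw centre identifier."""


class CapacityError(TrialmonError):
    """More centres than the acronym space can accommodate."""


class AppendOnlyError(TrialmonError):
    """Attempt to rewrite an existing entry of the append-only log."""
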