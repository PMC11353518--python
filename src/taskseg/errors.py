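"""Exception hierarchy for taskseg."""


class TasksegError(Exception):
    """Base class for all taskseg errors."""


class ParseError(TasksegError):
    """A log or annotation file could not be parsed."""


class ValidationError(TasksegError):
    """Parsed data violates a structural invariant."""


class ConfigurationError(TasksegError):
    """Thresholds or generator parameters are inconsistent."""


class EstimationError(TasksegError):
    """Too little data to estimate a quantity."""
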