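"""Exception hierarchy for runsync."""


class RunsyncError(Exception):
    """Base class for all runsync errors."""


class ConfigurationError(RunsyncError, ValueError):
    """Invalid parameter, distribution or design configuration."""


class SimulationError(RunsyncError, RuntimeError):
    """A simulation left its physically plausible operating range."""


class InsufficientHistoryError(RunsyncError, ValueError):
    """Not enough past events to compute the requested quantity."""


class EventLogParseError(RunsyncError, ValueError):
    """Malformed event-log file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
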