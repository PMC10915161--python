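"""Exception hierarchy."""


class HydrotwinError(Exception):
    """Base class for all package errors."""


class ValidationError(HydrotwinError, ValueError):
    """An input value violates its documented range or consistency rule."""


class TwinBuildError(HydrotwinError):
    """A stage of the twin-building pipeline failed.

    Carries the name of the failing stage so a caller can tell which
    measured quantity is inconsistent.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"twin build stage '{stage}': {message}")


class ConfigError(HydrotwinError, ValueError):
    """An athlete/twin config file is malformed (bad key, unit or value)."""


class RecordError(HydrotwinError, ValueError):
    """A power record file or series is malformed."""


class SimulationError(HydrotwinError):
    """The integrator met a non-finite state or an unstable step size."""
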