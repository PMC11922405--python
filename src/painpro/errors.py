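"""Exception hierarchy shared across the package."""


class PainProError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PainProError):
    """Input data does not conform to the registry data dictionary."""


class ConfigError(PainProError):
    """Invalid simulation or pipeline configuration.

    Carries the full list of violations so callers see every problem at
    once rather than one per run.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ConvergenceError(PainProError):
    """A model fit failed to converge."""
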