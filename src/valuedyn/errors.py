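"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class SeparationError(ValueError):
    """A choice model hit (quasi-)complete separation; its coefficient
    magnitudes are unusable."""


class NoSolutionError(RuntimeError):
    """A requested quantity does not exist for the given data
    (e.g. a calibration curve that never reaches the target rating)."""


class ConfigError(ValueError):
    """Pipeline configuration failed validation.

    Carries the full list of problems so a user can fix them all at once.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))
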