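"""Exception types shared across pipeline stages."""


class ConfigurationError(ValueError):
    """An invalid parameter or configuration value, raised before any compute."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending case ids."""

    def __init__(self, stage: str, message: str, case_ids=()):
        self.stage = stage
        self.case_ids = list(case_ids)
        suffix = f" (cases: {', '.join(self.case_ids)})" if self.case_ids else ""
        super().__init__(f"[{stage}] {message}{suffix}")
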