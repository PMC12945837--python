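"""Exception types shared across the package."""


class PvscreenError(Exception):
    """Base class for all package errors."""


class FormatError(PvscreenError):
    """An input table is malformed (e.g. a mandatory column is missing)."""


class MappingError(PvscreenError):
    """A preferred term has no entry in the PT->SOC hierarchy."""

    def __init__(self, missing_pts):
        self.missing_pts = sorted(missing_pts)
        super().__init__(
            "preferred terms missing from the PT->SOC hierarchy: "
            + ", ".join(self.missing_pts)
        )


class ConfigError(PvscreenError):
    """A configuration object failed validation."""


class RuleError(ConfigError):
    """A signal-rule expression could not be parsed."""
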