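"""Exception hierarchy shared across the package."""


class HetflagError(Exception):
    """Base class for all package-specific errors."""


class GtfParseError(HetflagError):
    """A GTF line violates the format contract; message names the line number."""


class ConfigError(HetflagError):
    """An analysis or simulation parameter is outside its valid range."""


class DegenerateDataError(HetflagError):
    """Input data cannot support the requested computation (too few or
    constant values)."""


class NonConvergenceError(HetflagError):
    """An iterative fit failed: component collapse, variance-floor hit or
    iteration budget exhausted."""


class MissingGeneError(HetflagError, KeyError):
    """Gene ids required by an operation are absent from a lookup table."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} gene id(s) missing: {', '.join(self.missing[:10])}"
            + ("…" if len(self.missing) > 10 else "")
        )
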