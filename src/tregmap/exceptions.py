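"""Exception hierarchy for tregmap."""


class TregmapError(Exception):
    """Base class for all tregmap errors."""


class ConfigurationError(TregmapError):
    """A scenario or pulse configuration is inconsistent or incomplete."""


class ParameterError(TregmapError, ValueError):
    """A model parameter is outside its admissible range."""


class ValidationError(TregmapError, ValueError):
    """An input table violates the cohort schema."""


class FitError(TregmapError, RuntimeError):
    """A numerical fit failed to converge."""
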