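"""Exception hierarchy for fazseg."""


class FazSegError(Exception):
    """Base class for all fazseg errors."""


class ParameterError(FazSegError, ValueError):
    """A scene or operation parameter violates its stated domain."""


class ValidationError(FazSegError, ValueError):
    """An input object (annotation, mask, proposal) fails an invariant."""


class FormatError(FazSegError, ValueError):
    """A file is not in the expected on-disk format."""


class ConfigurationError(FazSegError):
    """The pipeline configuration is missing or inconsistent."""


class SelectionError(FazSegError):
    """No mask proposal could be selected for an image."""
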