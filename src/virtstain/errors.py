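"""Exception hierarchy shared across the pipeline stages."""


class VirtstainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VirtstainError):
    """A parameter value violates a stage's contract."""


class InputError(VirtstainError):
    """Input data is malformed or inconsistent."""


class RegistrationError(VirtstainError):
    """Keypoint registration of an image pair failed."""


class NumericError(VirtstainError):
    """A computed quantity became non-finite."""
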