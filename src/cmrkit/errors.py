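"""Exception and warning types shared across cmrkit."""


class CmrkitError(Exception):
    """Base class for all cmrkit errors."""


class DomainError(CmrkitError, ValueError):
    """An input lies outside the physical/physiological domain of an operation."""


class ConfigurationError(CmrkitError, ValueError):
    """A model or pipeline configuration is invalid or incomplete."""


class InputError(CmrkitError, ValueError):
    """Structurally invalid data (shape mismatch, empty mask, missing column...)."""


class FitError(CmrkitError, RuntimeError):
    """A model fit failed or produced a non-physical result."""


class EstimationError(CmrkitError, RuntimeError):
    """A derived quantity could not be estimated (e.g. no physiologic root)."""


class NumericalError(CmrkitError, RuntimeError):
    """A numerical routine failed to converge."""


class ValidityError(CmrkitError, ValueError):
    """A closed-form model was evaluated outside its validity branch."""


class ExtrapolationWarning(UserWarning):
    """A calibration was evaluated outside its tabulated range."""
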