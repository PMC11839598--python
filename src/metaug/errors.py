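"""Exception hierarchy shared across metaug modules."""


class MetaugError(Exception):
    """Base class for all metaug errors."""


class ConfigurationError(MetaugError, ValueError):
    """Invalid configuration values (probabilities out of range, bad sizes...)."""


class InputError(MetaugError, ValueError):
    """Invalid runtime input (empty text, unknown ids, dimension mismatch...)."""


class IntegrityError(MetaugError, ValueError):
    """Provenance or split-integrity violation."""


class NumericError(MetaugError, ArithmeticError):
    """Non-finite values encountered during numerical computation."""


class StateError(MetaugError, RuntimeError):
    """Operation invalid in the current object state (e.g. double LoRA merge)."""
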