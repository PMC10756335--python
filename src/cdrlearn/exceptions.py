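"""Exception hierarchy: validation problems vs runtime/numerical failures."""


class CdrLearnError(Exception):
    """Base class for all package errors."""


class ValidationError(CdrLearnError, ValueError):
    """Malformed or inconsistent input data / shapes."""


class ConfigError(CdrLearnError, ValueError):
    """Invalid hyperparameter combination (e.g. alpha + beta != 1)."""


class FeaturizationError(CdrLearnError, ValueError):
    """A SMILES string could not be turned into a molecular graph."""


class TrainingError(CdrLearnError, RuntimeError):
    """Numerical failure during optimization (NaN loss, degenerate fold)."""
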