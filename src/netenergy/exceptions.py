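"""Exception hierarchy for trial-table validation and model fitting."""


class NetEnergyError(Exception):
    """Base class for all package errors."""


class SchemaError(NetEnergyError):
    """A required column is missing or a file cannot be parsed."""


class ValidationError(NetEnergyError):
    """A field value violates a stated invariant; the message names the row."""


class UnknownGroupError(NetEnergyError):
    """A record references a feeding-level label absent from the design."""


class RankError(NetEnergyError):
    """Predictors are collinear or the design matrix is rank deficient."""


class DegreesOfFreedomError(NetEnergyError):
    """Too few observations for the number of coefficients requested."""


class SimulationError(NetEnergyError):
    """A parameter combination produced a physically impossible trajectory."""
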