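"""Exception types shared across the package."""


class FlowmissError(Exception):
    """Base class for package errors."""


class ConfigurationError(FlowmissError):
    """Invalid prior, model, network or training configuration."""


class SimulationError(FlowmissError):
    """A simulator failed; carries the offending parameters/index in args."""


class TrainingError(FlowmissError):
    """Non-finite loss or diverged optimisation."""
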