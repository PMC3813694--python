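"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A scenario or parameter configuration violates its contract."""


class SimulationError(RuntimeError):
    """The simulator reached an invalid internal state (NaN/negative abundance)."""


class DegenerateOutputError(ValueError):
    """An output variable has zero variance; sensitivity indices are undefined."""
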