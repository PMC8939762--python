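"""Exception types shared across the toolkit."""


class InvalidParameterError(ValueError):
    """A physical or geometric parameter is outside its valid domain."""


class GridError(ValueError):
    """A simulation grid is too coarse or otherwise unusable."""


class ConfigError(ValueError):
    """A configuration mapping failed schema or unit-suffix validation."""


class GCodeError(ValueError):
    """A G-code document contains words the planner cannot interpret."""
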