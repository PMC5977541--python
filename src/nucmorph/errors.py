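"""Package-level exception types."""


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain (non-finite, negative, ...)."""


class UndefinedFeatureError(ValueError):
    """A feature is undefined for the given input (too few points, degenerate)."""


class ParseError(ValueError):
    """An input file is malformed (bad geometry, overlapping labels, ...)."""


class GenerationError(RuntimeError):
    """Synthetic generation could not satisfy its constraints within budget."""
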