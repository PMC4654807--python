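"""Exception types shared across the pipeline stages."""


class ThLineageError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(ThLineageError, ValueError):
    """Invalid user input: bad config value, out-of-range p-value, etc."""


class DegenerateInputError(ThLineageError, ValueError):
    """Input too small or too degenerate for the requested fit."""


class PlacementError(ThLineageError, ValueError):
    """Synthetic genome too small to place the requested features."""


class StageError(ThLineageError, RuntimeError):
    """A pipeline stage failed; message carries the stage name."""
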