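"""Exception types shared across the package.

Validation failures (bad parameters, malformed annotations) and I/O
failures are kept distinct so the CLI can map them to different exit
codes.
"""


class ValidationError(ValueError):
    """A parameter or input value violates a documented precondition."""


class GenerationError(RuntimeError):
    """The synthetic generator could not satisfy its placement constraints."""
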