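"""Exception hierarchy.

Every hard error the pipeline raises deliberately is a :class:`LithoscreenError`
(or a subclass), so callers and the CLI can distinguish malformed input from
programming bugs.
"""


class LithoscreenError(Exception):
    """Base class for all errors raised deliberately by lithoscreen."""


class FormatError(LithoscreenError):
    """An input file violates its format contract (parse errors, bad values)."""


class ValidationError(LithoscreenError):
    """An in-memory object violates an invariant (duplicate ids, bad ranges)."""
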