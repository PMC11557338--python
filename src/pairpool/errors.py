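"""Exception hierarchy for pairpool."""


class PairpoolError(Exception):
    """Base class for all pairpool errors."""


class ValidationError(PairpoolError, ValueError):
    """An input violates a documented invariant."""


class InfeasibleDesignError(ValidationError):
    """The requested pooling design cannot satisfy its constraints."""


class ParseError(PairpoolError, ValueError):
    """An on-disk file does not conform to its expected dialect."""
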