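"""Exception hierarchy shared across the package."""


class CstkitError(Exception):
    """Base class for all cstkit errors."""


class SchemaError(CstkitError, ValueError):
    """A table is missing or misnames a mandatory column."""


class ParseError(CstkitError, ValueError):
    """A cell could not be parsed; message carries row/column coordinates."""


class ValidationError(CstkitError, ValueError):
    """Data violates an invariant (duplicate ids, bad row sums, bad labels)."""


class DegenerateCompositionError(CstkitError, ValueError):
    """A composition vector is all-zero or off the probability simplex."""


class NameCollisionError(CstkitError, ValueError):
    """Two clusters derived the same sub-CST name under collision='error'."""
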