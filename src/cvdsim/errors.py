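"""Exception types shared across cvdsim modules."""


class CvdsimError(Exception):
    """Base class for all cvdsim errors."""


class SpecificationError(CvdsimError, ValueError):
    """A model specification is malformed (unknown symbol, bad flow wiring, ...)."""


class NumericError(CvdsimError, ArithmeticError):
    """A rate or level became non-finite during simulation."""


class DomainError(CvdsimError, ValueError):
    """An argument is outside its scientifically meaningful domain."""


class UnitError(CvdsimError, ValueError):
    """Quantities with incompatible units or cost base years were combined."""


class InsufficientDataError(CvdsimError, ValueError):
    """Too few observations to compute a diagnostic."""
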