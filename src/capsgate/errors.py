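"""Exception and warning hierarchy.

All errors raised on bad inputs derive from :class:`CapsgateError` so callers
can catch the package's failures with a single except clause; ``ParameterError``
additionally derives from ``ValueError`` to behave like ordinary argument
validation.
"""


class CapsgateError(Exception):
    """Base class for all package errors."""


class ParameterError(CapsgateError, ValueError):
    """An argument is outside its physical or logical domain."""


class ConfigurationError(CapsgateError):
    """Inconsistent acquisition or pipeline configuration (e.g. undersampling)."""


class FitError(CapsgateError):
    """A nonlinear fit failed to converge or its result is untrustworthy."""


class DegenerateFitError(FitError):
    """The data do not support the fitted model (e.g. unimodal amplitude data)."""


class IdentifiabilityError(FitError):
    """Parameters cannot be separated from the data.

    The canonical case: at saturating agonist the maximal open probability
    approaches unity, so the denominator (1 - Po_max) of the gating-constant
    estimator becomes very small and L (hence K_D) is unreliable.
    """


class NoReversalError(CapsgateError):
    """The current never changes sign within the voltage ramp."""


class AmbiguousReversalError(CapsgateError):
    """Multiple zero crossings in the ramp; candidates are attached."""

    def __init__(self, msg, candidates):
        super().__init__(msg)
        self.candidates = list(candidates)


class PDBParseError(CapsgateError, ValueError):
    """Malformed fixed-column PDB record; carries the 1-based line number."""

    def __init__(self, msg, line_number=None):
        super().__init__(msg)
        self.line_number = line_number


class PairingError(CapsgateError):
    """Atom selections of two structures cannot be put in 1:1 correspondence."""


class MissingAtomError(CapsgateError):
    """A named residue or atom required for a measurement is absent."""


class IdentifiabilityWarning(UserWarning):
    """The fit sits on the flat L-K_D ridge (Po_max near 1)."""
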