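"""Typed exceptions shared across contphy."""


class ContphyError(Exception):
    """Base class for all contphy errors."""


class TreeParseError(ContphyError):
    """Malformed serialized tree input."""


class ValidationError(ContphyError):
    """Input violates a documented invariant."""


class TaxonLookupError(ContphyError, KeyError):
    """A requested taxon label is not present in the tree."""


class SingularCovarianceError(ContphyError):
    """A covariance matrix required to be invertible is (numerically) singular.

    MCMC callers are expected to convert this into a proposal rejection
    rather than letting it propagate.
    """


class SimulationError(ContphyError):
    """A conditioned stochastic simulation failed within its retry budget."""
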