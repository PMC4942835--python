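"""Exception hierarchy used across the package."""


class SbsfoldError(Exception):
    """Base class for all package errors."""


class InvalidModelError(SbsfoldError):
    """A polymer/binder system violates a structural precondition."""


class UnitMappingError(SbsfoldError):
    """A physical-unit conversion was requested without the required mapping."""


class CongestionError(SbsfoldError):
    """Chain or binder placement failed after bounded retries."""


class OverstretchError(SbsfoldError):
    """A FENE bond reached or exceeded its maximum extension."""


class SingularityError(SbsfoldError):
    """Two particles are too close for a finite force evaluation."""


class InstabilityError(SbsfoldError):
    """Integration produced non-finite coordinates."""


class EmptyInputError(SbsfoldError):
    """An observable was requested on an empty trajectory or ensemble."""


class FitDomainError(SbsfoldError):
    """Data fall outside the domain of a fit (nonpositive values, no overlap)."""


class DomainError(SbsfoldError):
    """An index or separation falls outside the valid domain."""


class NotConvergedError(SbsfoldError):
    """A diagnostic indicates the system has not equilibrated."""


class MislabeledStateError(SbsfoldError):
    """Simulation parameters do not produce the thermodynamic state they claim."""


class WavevectorError(SbsfoldError):
    """Requested wavevectors are not commensurate with the periodic box."""


class InvalidVariantError(SbsfoldError):
    """A structural variant would produce an invalid chain."""


class AlignmentError(SbsfoldError):
    """Two matrices do not share shape, bins, or masks."""


class FormatError(SbsfoldError):
    """A file violates the expected on-disk format."""


class OracleScopeError(SbsfoldError):
    """A brute-force oracle was called beyond its size guard."""
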