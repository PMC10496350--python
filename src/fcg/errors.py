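"""Exception taxonomy shared across the package."""


class FcgError(Exception):
    """Base class for package errors."""


class CapacityError(FcgError):
    """Input exceeds the slot capacity of a ciphertext."""


class AlignmentError(FcgError):
    """Operands disagree on scale or remaining multiplicative level."""


class DepthError(FcgError):
    """Multiplicative budget exhausted; a collective refresh is needed."""


class CapabilityError(FcgError):
    """The active backend or key material lacks a required capability."""


class ShapeError(FcgError):
    """Matrix shapes incompatible with the requested operation."""


class ProtocolError(FcgError):
    """A multiparty protocol contract was violated."""


class IncompleteError(ProtocolError):
    """Not all sites contributed to a collective step."""


class StallError(ProtocolError):
    """A required file never appeared in the shared space."""


class TamperError(ProtocolError):
    """Authenticated payload failed verification."""


class KeyMaterialError(FcgError):
    """Key share or parameters inconsistent with the ciphertext."""


class ConditionError(FcgError):
    """A matrix to be inverted is numerically singular."""
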