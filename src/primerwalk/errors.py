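"""Exception hierarchy for primerwalk.

Every error a caller can act on derives from :class:`PrimerwalkError`, so
``except PrimerwalkError`` at a batch or CLI boundary catches all anticipated
failure modes while letting genuine bugs propagate.
"""

from __future__ import annotations


class PrimerwalkError(Exception):
    """Base class for all anticipated primerwalk failures."""


class AlphabetError(PrimerwalkError):
    """A sequence contains characters outside the strict A/C/G/T alphabet."""


class LengthError(PrimerwalkError):
    """A sequence is too short for the requested operation (duplexes need >= 2 nt)."""


class SaltError(PrimerwalkError):
    """Monovalent-equivalent cation concentration is non-positive; the entropic
    salt correction is undefined."""


class KModeError(PrimerwalkError):
    """The equilibrium-constant mode is unknown or its preconditions fail
    (e.g. excess-primer mode with template/2 >= primer)."""


class NumericalError(PrimerwalkError):
    """A melting-temperature denominator came out non-negative: the duplex has
    no melting transition under the supplied conditions."""


class TemplateTooShortError(PrimerwalkError):
    """Template is shorter than the minimum annealing length."""


class NoCandidateError(PrimerwalkError):
    """No boundary-anchored primer length reaches the Tm tolerance window.

    Carries ``nearest_tm``, the achievable Tm closest to the optimum, as a
    diagnostic for the user.
    """

    def __init__(self, message: str, nearest_tm: float | None = None):
        super().__init__(message)
        self.nearest_tm = nearest_tm


class DesignFailure(PrimerwalkError):
    """A single record could not be designed; wraps the underlying cause.

    Batch runs catch this, record it, and continue with the remaining records.
    """

    def __init__(
        self,
        record_id: str,
        orientation: str,
        reason: str,
        nearest_tm: float | None = None,
    ):
        super().__init__(f"{record_id} ({orientation}): {reason}")
        self.record_id = record_id
        self.orientation = orientation
        self.reason = reason
        self.nearest_tm = nearest_tm


class DuplicateIdError(PrimerwalkError):
    """Two records in a batch share an identifier."""


class FastaFormatError(PrimerwalkError):
    """Input does not parse as FASTA (no leading '>' or an empty record body)."""


class PresetNotFoundError(PrimerwalkError):
    """Requested buffer preset name is not in the registry."""


class InsufficientDataError(PrimerwalkError):
    """Fewer than two usable benchmark records, or zero variance in the
    predictor — no regression can be fit."""


class ParameterError(PrimerwalkError):
    """Invalid fixture-generator or configuration parameters."""
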