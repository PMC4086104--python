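"""Boundary-anchored primer design.

Amplicon boundaries are fixed at the ends of each input record (e.g. start
codon to stop codon), so the only design freedom is how far each primer
reaches into the template.  The walker therefore evaluates, for each
orientation, every annealing length between ``min_len`` and ``max_len``:
the forward candidate of length L is the template prefix of length L, the
reverse candidate is the reverse complement of the suffix of length L.
Candidates whose predicted Tm falls inside the tolerance window around the
optimum are kept, ranked, and the best pair is assembled with the user's
5'-extensions prepended verbatim.

Ranking minimises |Tm - optimum|; when a G/C 3'-end ("clamp") is requested,
clamped candidates win over unclamped ones whenever any clamped candidate is
in the window.  Ties on |dTm| break to the shorter candidate (cheaper
synthesis), then to the clamped one.

A record whose window is unreachable fails with a diagnostic carrying the
nearest achievable Tm; batch runs collect failures and continue.  An
optional auto-widen step relaxes the window iteratively instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import (
    AlphabetError,
    DesignFailure,
    DuplicateIdError,
    NoCandidateError,
    TemplateTooShortError,
)
from .thermo import (
    BufferConditions,
    NNParameterSet,
    _check_sequence,
    melting_temperature,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Hard ceiling for auto-widening, deg C. Beyond this the window spans most
#: of the practically relevant Tm range and failing loudly is more useful.
MAX_AUTO_WIDEN_TOLERANCE = 25.0


def reverse_complement(sequence: str) -> str:
    """Watson-Crick complement, reversed (strict A/C/G/T)."""
    bad = sorted(set(sequence) - set("ACGT"))
    if bad:
        raise AlphabetError(
            f"sequence contains characters outside A/C/G/T: {''.join(bad)!r}"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignSpec:
    """User constraints for a design run.

    ``tm_optimal``/``tm_tolerance`` define the acceptance window in deg C;
    ``force_gc_clamp`` prefers primers ending in G or C; the extensions are
    prepended verbatim to the annealing regions (they never enter the Tm
    computation); ``min_len``/``max_len`` bound the annealing length in nt.
    """

    tm_optimal: float = 60.0
    tm_tolerance: float = 5.0
    force_gc_clamp: bool = True
    ext_forward: str = ""
    ext_reverse: str = ""
    min_len: int = 15
    max_len: int = 40

    def __post_init__(self) -> None:
        if self.tm_tolerance <= 0:
            raise ValueError(f"tm_tolerance must be > 0, got {self.tm_tolerance}")
        if not (2 <= self.min_len <= self.max_len):
            raise ValueError(
                f"need 2 <= min_len <= max_len, got {self.min_len}..{self.max_len}"
            )
        for label, ext in (("ext_forward", self.ext_forward), ("ext_reverse", self.ext_reverse)):
            bad = sorted(set(ext) - set("ACGT"))
            if bad:
                raise AlphabetError(
                    f"{label} contains characters outside A/C/G/T: {''.join(bad)!r}"
                )


@dataclass(frozen=True)
class PrimerCandidate:
    """One boundary-anchored annealing region with its predicted Tm."""

    annealing_seq: str
    length: int
    tm: float
    ends_gc: bool
    orientation: str  # "forward" | "reverse"


@dataclass(frozen=True)
class PrimerPair:
    """A designed forward/reverse pair with extensions attached."""

    record_id: str
    forward_full: str
    reverse_full: str
    forward_candidate: PrimerCandidate
    reverse_candidate: PrimerCandidate
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _scan(
    template: str,
    orientation: str,
    spec: DesignSpec,
    params: NNParameterSet,
    buffer: BufferConditions,
) -> list[PrimerCandidate]:
    """Evaluate every allowed annealing length at one boundary (no window
    filter); ordered by increasing length."""
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    if len(template) < spec.min_len:
        raise TemplateTooShortError(
            f"template of length {len(template)} is shorter than min_len {spec.min_len}"
        )
    _check_sequence(template, min_len=spec.min_len)
    out = []
    for length in range(spec.min_len, min(spec.max_len, len(template)) + 1):
        if orientation == "forward":
            seq = template[:length]
        else:
            seq = reverse_complement(template[-length:])
        tm = melting_temperature(seq, params, buffer).tm_celsius
        out.append(
            PrimerCandidate(
                annealing_seq=seq,
                length=length,
                tm=tm,
                ends_gc=seq[-1] in "GC",
                orientation=orientation,
            )
        )
    return out


def enumerate_candidates(
    template: str,
    orientation: str,
    spec: DesignSpec,
    params: NNParameterSet,
    buffer: BufferConditions,
) -> list[PrimerCandidate]:
    """All boundary-anchored candidates whose Tm is inside the tolerance
    window, ordered by increasing annealing length."""
    if len(template) < spec.min_len:
        raise TemplateTooShortError(
            f"template of length {len(template)} is shorter than min_len {spec.min_len}"
        )
    return [
        c
        for c in _scan(template, orientation, spec, params, buffer)
        if abs(c.tm - spec.tm_optimal) <= spec.tm_tolerance
    ]


def _rank_key(candidate: PrimerCandidate, tm_optimal: float):
    return (abs(candidate.tm - tm_optimal), candidate.length, not candidate.ends_gc)


def rank_and_pick(
    candidates: list[PrimerCandidate], spec: DesignSpec
) -> tuple[PrimerCandidate, list[str]]:
    """Pick the best candidate under the clamp constraint.

    With the clamp forced, a G/C-ending candidate closest to the optimum
    wins; if none ends in G/C the global best is returned with an advisory
    warning.  Without the clamp the global best wins outright.
    """
    if not candidates:
        raise NoCandidateError("no candidate inside the Tm tolerance window")
    warnings: list[str] = []
    pool = candidates
    if spec.force_gc_clamp:
        clamped = [c for c in candidates if c.ends_gc]
        if clamped:
            pool = clamped
        else:
            warnings.append(
                f"no G/C clamp available among {len(candidates)} in-window "
                f"{candidates[0].orientation} candidates"
            )
    return min(pool, key=lambda c: _rank_key(c, spec.tm_optimal)), warnings


def _design_one_end(
    record_id: str,
    template: str,
    orientation: str,
    spec: DesignSpec,
    params: NNParameterSet,
    buffer: BufferConditions,
    auto_widen: float | None,
) -> tuple[PrimerCandidate, list[str]]:
    try:
        scan = _scan(template, orientation, spec, params, buffer)
    except (TemplateTooShortError, AlphabetError) as exc:
        raise DesignFailure(record_id, orientation, str(exc)) from exc

    tolerance = spec.tm_tolerance
    widened = False
    while True:
        in_window = [c for c in scan if abs(c.tm - spec.tm_optimal) <= tolerance]
        if in_window:
            picked, warnings = rank_and_pick(in_window, replace(spec, tm_tolerance=tolerance))
            if widened:
                warnings.append(
                    f"tolerance widened to +/-{tolerance:g} degC to reach a candidate"
                )
            return picked, warnings
        nearest = min(scan, key=lambda c: abs(c.tm - spec.tm_optimal))
        if auto_widen and tolerance + auto_widen <= MAX_AUTO_WIDEN_TOLERANCE:
            tolerance += auto_widen
            widened = True
            continue
        raise DesignFailure(
            record_id,
            orientation,
            f"no annealing length {spec.min_len}-{spec.max_len} nt reaches "
            f"{spec.tm_optimal:g} +/- {tolerance:g} degC "
            f"(nearest achievable Tm: {nearest.tm:.2f} degC at {nearest.length} nt)",
            nearest_tm=nearest.tm,
        )


def _as_id_template(record) -> tuple[str, str]:
    """Accept either an ``(id, template)`` tuple or any object exposing
    ``.id`` and ``.sequence`` (e.g. an I/O SequenceRecord)."""
    if hasattr(record, "id") and hasattr(record, "sequence"):
        return record.id, record.sequence
    return record[0], record[1]


def design_pair(
    record: tuple[str, str],
    spec: DesignSpec,
    params: NNParameterSet,
    buffer: BufferConditions,
    auto_widen: float | None = None,
) -> PrimerPair:
    """Design the forward/reverse pair for one ``(id, template)`` record.

    The amplicon implied by the returned pair is exactly the input template:
    stripping the extensions leaves an exact template prefix and an exact
    reverse-complemented suffix.
    """
    record_id, template = _as_id_template(record)
    fwd, fwd_warn = _design_one_end(
        record_id, template, "forward", spec, params, buffer, auto_widen
    )
    rev, rev_warn = _design_one_end(
        record_id, template, "reverse", spec, params, buffer, auto_widen
    )
    return PrimerPair(
        record_id=record_id,
        forward_full=spec.ext_forward + fwd.annealing_seq,
        reverse_full=spec.ext_reverse + rev.annealing_seq,
        forward_candidate=fwd,
        reverse_candidate=rev,
        warnings=tuple(fwd_warn + rev_warn),
    )


def design_batch(
    records: list[tuple[str, str]],
    spec: DesignSpec,
    params: NNParameterSet,
    buffer: BufferConditions,
    auto_widen: float | None = None,
) -> tuple[list[PrimerPair], list[DesignFailure]]:
    """Order-preserving map of :func:`design_pair` over a batch.

    Failures are collected, never raised past the batch boundary.  Duplicate
    record ids are rejected before any design work.
    """
    ids = [_as_id_template(r)[0] for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise DuplicateIdError(f"duplicate record ids in batch: {dupes}")
    pairs: list[PrimerPair] = []
    failures: list[DesignFailure] = []
    for record in records:
        try:
            pairs.append(design_pair(record, spec, params, buffer, auto_widen))
        except DesignFailure as failure:
            failures.append(failure)
    return pairs, failures
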